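"""Generators: determinism, fidelity to the forward models, packaged tables."""

import hashlib
from importlib import resources

import numpy as np
import pytest

from bilayermech.dib import bilayer_tension_from_replicates
from bilayermech.errors import InfeasibleTensionError, InsufficientReplicatesError
from bilayermech.stretching import CoverageModel, MembraneModel, predict_tension
from bilayermech.synthetic import (
    CONCENTRATIONS_UG_PER_ML,
    PLASTICS,
    POLLUTANTS,
    gen_brownian_tracks,
    gen_dib_angles,
    gen_droplet_profile,
    gen_tension_series,
    table_fixtures,
)

# frozen digests of the packaged measurement tables
_TABLE_SHA256 = {
    "table1_ps.csv": "7cb16614d435b8c93b88b4791347ba91cdb994594931e2a309b787b9543dd9ec",
    "table2_pe.csv": "08e793e266b51beab9298beea4301aefeacf56c7dc1a2b32d87b44332cac1fc8",
    "table3_pa.csv": "7eedaee0d54ffb5a548dd18947466ef6a4ecff7921c11bb71dbb092c7640fc79",
}


def test_tension_series_noise_free_lies_on_model():
    s = gen_tension_series(zeta=-0.05, K_half=120.0, gamma0=1.7, noise_sigma=0.0)
    mem = MembraneModel(k=200.0, zeta=-0.05, gamma0=1.7)
    cov = CoverageModel(phi_max=1.0, K_half=120.0)
    assert np.allclose(s.gamma_bilayer, predict_tension(s.concentrations, mem, cov))


def test_tension_series_zero_adhesion_is_flat():
    s = gen_tension_series(zeta=0.0, K_half=120.0, gamma0=1.7, noise_sigma=0.0)
    assert np.allclose(s.gamma_bilayer, 1.7)


def test_dib_angles_noise_free_reproduce_tension():
    reps = gen_dib_angles(1.7, 2.0, n=10, angle_noise_deg=0.0, seed=0)
    angles = {m.full_angle_2theta for m in reps}
    assert len(angles) == 1
    est = bilayer_tension_from_replicates(reps)
    assert est.gamma_bilayer == pytest.approx(1.7, abs=1e-10)


def test_dib_angles_sampling_statistics():
    reps = gen_dib_angles(1.7, 2.0, n=25, angle_noise_deg=2.0, seed=7)
    est = bilayer_tension_from_replicates(reps)
    assert abs(est.gamma_bilayer - 1.7) < 3 * est.sem


def test_dib_angles_infeasible_pair_rejected():
    with pytest.raises(InfeasibleTensionError):
        gen_dib_angles(4.5, 2.0, n=5)


def test_single_replicate_fails_downstream():
    reps = gen_dib_angles(1.7, 2.0, n=1, angle_noise_deg=0.0)
    with pytest.raises(InsufficientReplicatesError):
        bilayer_tension_from_replicates(reps)


def test_brownian_zero_diffusion_is_immobile():
    tracks = gen_brownian_tracks(0.0, n_particles=3, n_steps=20, dt=0.1, seed=0)
    for tr in tracks:
        assert np.all(tr.x == 0.0) and np.all(tr.y == 0.0)


@pytest.mark.parametrize(
    "make",
    [
        lambda s: gen_tension_series(-0.05, 120.0, 1.7, noise_sigma=0.3, seed=s).gamma_bilayer,
        lambda s: np.array(
            [m.full_angle_2theta for m in gen_dib_angles(1.7, 2.0, 10, 2.0, seed=s)]
        ),
        lambda s: gen_droplet_profile(2.0, 1.0, coord_noise_um=2.0, seed=s).points,
        lambda s: gen_brownian_tracks(0.5, 3, 20, 0.1, 0.02, seed=s)[0].x,
    ],
    ids=["tension", "angles", "profile", "tracks"],
)
def test_generators_deterministic_per_seed(make):
    assert np.array_equal(make(123), make(123))
    assert not np.array_equal(make(123), make(124))


def test_table_fixtures_structure():
    fx = table_fixtures()
    assert len(fx) == 27
    for (plastic, pollutant), s in fx.items():
        assert plastic in PLASTICS and pollutant in POLLUTANTS
        assert tuple(s.concentrations) == CONCENTRATIONS_UG_PER_ML
        assert s.gamma_bilayer[0] == pytest.approx(1.7)  # bare bilayer baseline
        assert np.all(s.errors > 0)


def test_table_fixtures_match_printed_rows():
    fx = table_fixtures()
    ps_pbs = fx[("PS", "PBS")]
    assert np.allclose(ps_pbs.gamma_bilayer, [1.7, 1.9, 2.2, 2.5, 3.4, 4.2])
    assert np.allclose(ps_pbs.errors, [0.2, 0.2, 0.2, 0.3, 0.3, 0.4])
    ps_hex = fx[("PS", "hexane")]
    assert np.allclose(ps_hex.gamma_bilayer, [1.7, 2.5, 4.1, 4.8, 5.9, 6.2])


def test_table_files_checksummed():
    for fname, digest in _TABLE_SHA256.items():
        data = resources.files("bilayermech.data").joinpath(fname).read_bytes()
        assert hashlib.sha256(data).hexdigest() == digest
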