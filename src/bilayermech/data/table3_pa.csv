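plastic,pollutant,conc_ug_per_ml,gamma_mN_per_m,err_mN_per_m
PA,PBS,0,1.7,0.2
PA,PBS,50,1.9,0.2
PA,PBS,100,2.2,0.2
PA,PBS,150,2.5,0.3
PA,PBS,300,3.4,0.3
PA,PBS,500,4.2,0.4
PA,mercury,0,1.7,0.2
PA,mercury,50,1.8,0.2
PA,mercury,100,1.9,0.2
PA,mercury,150,2.3,0.3
PA,mercury,300,3.4,0.3
PA,mercury,500,4.2,0.4
PA,hexane,0,1.7,0.2
PA,hexane,50,3.2,0.5
PA,hexane,100,4.7,0.5
PA,hexane,150,5.1,0.5
PA,hexane,300,5.3,0.5
PA,hexane,500,5.9,0.5
PA,toluene,0,1.7,0.2
PA,toluene,50,3.1,0.5
PA,toluene,100,4.8,0.5
PA,toluene,150,5.7,0.5
PA,toluene,300,6.2,0.5
PA,toluene,500,6.3,0.5
PA,1-octanol,0,1.7,0.2
PA,1-octanol,50,2.8,0.5
PA,1-octanol,100,3.9,0.5
PA,1-octanol,150,4.9,0.5
PA,1-octanol,300,5.6,0.5
PA,1-octanol,500,6.3,0.5
PA,perfluoroctanol,0,1.7,0.2
PA,perfluoroctanol,50,3.1,0.4
PA,perfluoroctanol,100,4.3,0.4
PA,perfluoroctanol,150,5.8,0.5
PA,perfluoroctanol,300,6.2,0.5
PA,perfluoroctanol,500,6.3,0.5
PA,zonyl,0,1.7,0.2
PA,zonyl,50,2.3,0.3
PA,zonyl,100,2.8,0.3
PA,zonyl,150,3.3,0.4
PA,zonyl,300,3.2,0.4
PA,zonyl,500,3.3,0.5
PA,DDT,0,1.7,0.2
PA,DDT,50,2.6,0.2
PA,DDT,100,3.2,0.2
PA,DDT,150,3.3,0.3
PA,DDT,300,3.5,0.3
PA,DDT,500,4.2,0.4
PA,sunscreen,0,1.7,0.2
PA,sunscreen,50,2.1,0.3
PA,sunscreen,100,2.6,0.3
PA,sunscreen,150,3.4,0.4
PA,sunscreen,300,3.4,0.4
PA,sunscreen,500,3.4,0.5
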