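plastic,pollutant,conc_ug_per_ml,gamma_mN_per_m,err_mN_per_m
PS,PBS,0,1.7,0.2
PS,PBS,50,1.9,0.2
PS,PBS,100,2.2,0.2
PS,PBS,150,2.5,0.3
PS,PBS,300,3.4,0.3
PS,PBS,500,4.2,0.4
PS,mercury,0,1.7,0.2
PS,mercury,50,1.8,0.2
PS,mercury,100,2.2,0.2
PS,mercury,150,2.4,0.3
PS,mercury,300,3.3,0.3
PS,mercury,500,4.1,0.4
PS,hexane,0,1.7,0.2
PS,hexane,50,2.5,0.5
PS,hexane,100,4.1,0.5
PS,hexane,150,4.8,0.5
PS,hexane,300,5.9,0.5
PS,hexane,500,6.2,0.5
PS,toluene,0,1.7,0.2
PS,toluene,50,2.4,0.5
PS,toluene,100,3.7,0.5
PS,toluene,150,5.6,0.5
PS,toluene,300,5.9,0.5
PS,toluene,500,6.2,0.5
PS,1-octanol,0,1.7,0.2
PS,1-octanol,50,2.18,0.5
PS,1-octanol,100,3.3,0.5
PS,1-octanol,150,4.3,0.5
PS,1-octanol,300,4.3,0.5
PS,1-octanol,500,4.3,0.5
PS,perfluoroctanol,0,1.7,0.2
PS,perfluoroctanol,50,2.2,0.4
PS,perfluoroctanol,100,3.8,0.4
PS,perfluoroctanol,150,5.1,0.5
PS,perfluoroctanol,300,5.9,0.5
PS,perfluoroctanol,500,5.9,0.5
PS,zonyl,0,1.7,0.2
PS,zonyl,50,2.1,0.3
PS,zonyl,100,2.7,0.3
PS,zonyl,150,3.2,0.4
PS,zonyl,300,3.3,0.4
PS,zonyl,500,3.3,0.5
PS,DDT,0,1.7,0.2
PS,DDT,50,1.9,0.2
PS,DDT,100,2.2,0.2
PS,DDT,150,2.5,0.3
PS,DDT,300,3.4,0.3
PS,DDT,500,4.2,0.4
PS,sunscreen,0,1.7,0.2
PS,sunscreen,50,2.0,0.3
PS,sunscreen,100,2.6,0.3
PS,sunscreen,150,3.3,0.4
PS,sunscreen,300,3.3,0.4
PS,sunscreen,500,3.3,0.5
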