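plastic,pollutant,conc_ug_per_ml,gamma_mN_per_m,err_mN_per_m
PE,PBS,0,1.7,0.2
PE,PBS,50,1.9,0.2
PE,PBS,100,2.1,0.2
PE,PBS,150,2.5,0.3
PE,PBS,300,3.4,0.3
PE,PBS,500,4.2,0.4
PE,mercury,0,1.7,0.2
PE,mercury,50,1.8,0.2
PE,mercury,100,2.1,0.2
PE,mercury,150,2.7,0.3
PE,mercury,300,3.2,0.3
PE,mercury,500,4.2,0.4
PE,hexane,0,1.7,0.2
PE,hexane,50,2.9,0.5
PE,hexane,100,4.7,0.5
PE,hexane,150,5.2,0.5
PE,hexane,300,5.8,0.5
PE,hexane,500,6.1,0.5
PE,toluene,0,1.7,0.2
PE,toluene,50,3.1,0.5
PE,toluene,100,4.8,0.5
PE,toluene,150,5.1,0.5
PE,toluene,300,5.7,0.5
PE,toluene,500,6.0,0.5
PE,1-octanol,0,1.7,0.2
PE,1-octanol,50,2.8,0.5
PE,1-octanol,100,4.1,0.5
PE,1-octanol,150,4.3,0.5
PE,1-octanol,300,4.2,0.5
PE,1-octanol,500,4.3,0.5
PE,perfluoroctanol,0,1.7,0.2
PE,perfluoroctanol,50,2.9,0.4
PE,perfluoroctanol,100,4.6,0.4
PE,perfluoroctanol,150,5.3,0.5
PE,perfluoroctanol,300,5.6,0.5
PE,perfluoroctanol,500,5.8,0.5
PE,zonyl,0,1.7,0.2
PE,zonyl,50,2.1,0.3
PE,zonyl,100,2.8,0.3
PE,zonyl,150,3.3,0.4
PE,zonyl,300,3.4,0.4
PE,zonyl,500,3.4,0.5
PE,DDT,0,1.7,0.2
PE,DDT,50,1.9,0.2
PE,DDT,100,2.1,0.2
PE,DDT,150,2.5,0.3
PE,DDT,300,3.5,0.3
PE,DDT,500,4.3,0.4
PE,sunscreen,0,1.7,0.2
PE,sunscreen,50,2.1,0.3
PE,sunscreen,100,2.5,0.3
PE,sunscreen,150,3.2,0.4
PE,sunscreen,300,3.4,0.4
PE,sunscreen,500,3.4,0.5
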