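species,group,mean_flight_date,window_center_month,n_sites,n_site_years,r2,b_time_mode,b_time_lo,b_time_hi,b_space_mode,b_space_lo,b_space_hi,delta_b_mode,delta_b_lo,delta_b_hi
Thymelicus sylvestris,a,21 June,5,1033,6121,0.25,-6.41,-8.29,-4.74,-4.06,-5.10,-3.17,2.38,0.35,4.21
Hesperia comma,a,18 July,7,58,553,0.21,-4.35,-5.75,-3.14,2.26,-5.88,10.79,6.53,-1.62,15.46
Ochlodes sylvanus,a,5 June,5,1140,8126,0.16,-6.76,-8.18,-5.52,-0.15,-1.90,1.30,6.63,4.70,8.56
Erynnis tages,a,26 April,3,449,2785,0.26,-5.68,-6.71,-4.70,-1.79,-3.56,0.02,3.88,1.86,5.87
Pyrgus malvae,a,22 April,3,344,2041,0.10,-6.00,-7.11,-4.57,-1.44,-13.82,9.68,4.51,-7.70,16.14
Anthocharis cardamines,a,10 April,3,1209,7422,0.39,-7.21,-8.35,-6.09,-5.23,-6.75,-3.78,2.04,0.24,3.92
Callophrys rubi,a,23 April,3,514,2784,0.19,-5.42,-6.11,-4.59,3.66,1.31,6.43,9.12,6.42,11.85
Polyommatus coridon,a,10 July,6,233,1765,0.18,-5.22,-6.53,-3.78,-2.67,-6.75,1.01,2.47,-1.36,6.97
Limenitis camilla,a,15 June,5,278,1745,0.21,-7.83,-8.60,-6.86,-12.68,-25.73,5.73,-4.85,-19.12,12.4
Boloria selene,a,21 May,5,227,1228,0.29,-6.25,-8.19,-4.30,-6.26,-8.11,-4.08,-0.03,-2.63,2.71
Boloria euphrosyne,a,26 April,3,157,872,0.23,-6.96,-8.15,-5.71,-5.02,-9.11,-0.74,1.9,-2.23,6.24
Argynnis adippe,a,17 June,5,62,478,0.12,-6.22,-8.51,-4.69,-7.07,-19.11,4.66,-0.89,-12.39,11.59
Argynnis aglaja,a,19 June,5,447,2312,0.09,-4.62,-6.08,-3.04,-1.79,-3.22,-0.32,2.77,0.61,4.86
Argynnis paphia,a,26 June,5,519,2670,0.19,-5.53,-7.21,-3.84,-7.53,-10.18,-4.88,-2.01,-5.19,0.94
Euphydryas aurinia,a,3 May,4,87,474,0.38,-6.97,-9.35,-5.15,-8.24,-13.55,-2.69,-1.26,-7.05,4.78
Melanargia galathea,a,13 June,5,721,4866,0.37,-6.92,-8.13,-5.78,-4.72,-7.38,-2.33,2.21,-0.60,4.87
Hipparchia semele,a,6 July,5,231,1310,0.05,-3.74,-5.31,-2.37,1.20,-1.40,3.54,5.04,2.43,7.93
Pyronia tithonus,a,2 July,6,1142,8391,0.45,-6.13,-6.96,-5.33,-3.39,-4.41,-2.37,2.77,1.46,4.05
Maniola jurtina,a,23 June,5,1361,9876,0.13,-4.54,-5.93,-3.01,-1.04,-1.89,-0.10,3.51,1.84,5.28
Aphantopus hyperantus,a,13 June,5,1202,7546,0.37,-6.52,-7.38,-5.64,-2.02,-2.79,-1.42,4.51,3.42,5.58
Gonepteryx rhamni,b,11 July,7,877,5720,0.30,-8.31,-9.95,-6.77,-5.72,-7.78,-3.45,2.65,-0.17,5.27
Aglais io,b,8 July,5,1253,8273,0.53,-7.60,-9.71,-5.68,-8.82,-9.66,-7.9,-1.18,-3.38,0.82
Pieris rapae,c,20 April,4,1190,7325,0.31,-9.07,-10.74,-7.32,-3.72,-4.71,-2.8,5.38,3.35,7.37
Pieris napi,c,18 April,4,1214,7986,0.41,-8.21,-9.78,-6.90,-5.18,-5.89,-4.61,3.01,1.41,4.54
Pieris brassicae,c,25 April,4,1195,7239,0.29,-8.10,-9.51,-6.91,-5.45,-6.39,-4.34,2.67,0.84,4.23
Lycaena phlaeas,c,25 April,3,887,3739,0.31,-6.73,-7.75,-5.65,-4.35,-5.61,-2.99,2.40,0.78,4.06
Cupido minimus,c,8 May,3,169,938,0.28,-4.98,-6.32,-3.70,-4.65,-7.14,-2.07,0.32,-2.6,3.04
Aricia agestis,c,1 May,3,411,2005,0.30,-6.23,-7.30,-5.09,-5.68,-8.44,-3.08,0.56,-2.15,3.6
Polyommatus icarus,c,10 June,4,1104,6529,0.55,-7.04,-8.52,-5.21,-12.92,-14.55,-11.2,-5.90,-8.25,-3.66
Celastrina argiolus,c,12 May,3,908,4246,0.18,-5.89,-6.86,-4.83,-3.62,-6.43,-0.54,2.17,-0.91,5.36
Lasiommata megera,c,27 May,3,420,1981,0.39,-7.33,-8.09,-6.57,-6.14,-7.71,-4.57,1.18,-0.54,2.88
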