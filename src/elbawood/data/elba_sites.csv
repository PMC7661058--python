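id,name,t_alpha,t_beta,t_gamma,t_delta,slag_min,slag_max,x,y
1,Martella ant.,-360,-280,-211,-180,400,1400,,
2,Ombria,-300,-232,-93,-25,1000,5000,,
3,San Bennato,-300,-180,138,139,100,5000,,
4,Fornacelle,-140,-10,73,73,1000,5000,,
5,Capo Pero,-300,-201,-47,100,4400,13500,,
6,Fegatella,-300,-300,-25,-25,600,1900,,
7,Valle del Giove,-300,-140,-25,-10,600,1200,,
8,Vigneria,-300,-226,-75,-1,1000,5000,,
9,Rio Marina / Spiazzi,-225,-145,1,50,100,15000,,
10,Barbarossa,-260,-210,-120,-50,20500,20500,,
11,Naregno,-260,-248,-222,-210,1200,1200,,
12,Straccoligno,-260,-210,-200,-120,1000,1000,,
13,Lacona,-140,-140,-10,-10,600,1200,,
14,Galenzana,-130,-123,-107,-100,600,1200,,
15,Seccheto,-280,-217,-88,-25,2600,4300,,
16,Sughera,-280,-217,-88,-25,100,1000,,
17,Pomonte,-130,-100,-100,-50,4800,14700,,
18,Patresi,-260,-140,-120,-10,1000,2000,,
19,Sant'Andrea,-200,-120,-101,-10,10000,23000,,
20,Marciana Marina,-290,-240,-60,-10,9000,10500,,
21,Bagno,-220,-175,-85,-40,2000,10000,,
22,Paolina,-200,-135,-60,60,5000,15000,,
23,Gnacchera,-300,-232,-93,-25,1000,5000,,
24,Guardiola,-204,-140,-120,-10,1000,5000,,
25,Campo all'Aia,-130,-100,-60,-20,10800,10800,,
26,La Pila,-140,-108,-42,-10,300,600,,
27,Forcioni,-140,-50,-10,100,400,1800,,
28,San Giovanni,-200,-120,15,100,10500,14500,,
29,Magazzini,-300,-165,-60,60,200,4000,,
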