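# Photon mass attenuation coefficient table for material 'scintillator' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,2.348855199339e+06,1.686648714451e-01,0.000000000000e+00,2.348855368004e+06
1.118593076865e-03,1.678185109317e+06,1.685871200208e-01,0.000000000000e+00,1.678185277905e+06
1.251250471609e-03,1.199011868389e+06,1.685002557555e-01,0.000000000000e+00,1.199012036889e+06
1.399640114966e-03,8.566572617976e+05,1.684032285016e-01,0.000000000000e+00,8.566574302009e+05
1.565627742703e-03,6.120553795491e+05,1.682948659927e-01,0.000000000000e+00,6.120555478439e+05
1.751300353935e-03,4.372948252944e+05,1.681738683760e-01,0.000000000000e+00,4.372949934683e+05
1.958992451422e-03,3.124337610922e+05,1.680387895398e-01,0.000000000000e+00,3.124339291310e+05
2.191315393791e-03,2.232243544262e+05,1.678880263991e-01,0.000000000000e+00,2.232245223142e+05
2.451190228721e-03,1.594869652843e+05,1.677198005571e-01,0.000000000000e+00,1.594871330041e+05
2.741884419926e-03,1.139485526165e+05,1.675321448923e-01,0.000000000000e+00,1.139487201486e+05
3.067052929692e-03,8.141275131947e+04,1.673228823907e-01,0.000000000000e+00,8.141291864235e+04
3.430784173531e-03,5.816691765901e+04,1.670896098148e-01,0.000000000000e+00,5.816708474862e+04
3.837651424729e-03,4.155848138178e+04,1.668296770843e-01,0.000000000000e+00,4.155864821146e+04
4.292770315121e-03,2.969226227328e+04,1.665401671780e-01,0.000000000000e+00,2.969242881345e+04
4.801863155064e-03,2.121421210766e+04,1.662178757632e-01,0.000000000000e+00,2.121437832554e+04
5.371330881306e-03,1.515690489350e+04,1.658592906451e-01,0.000000000000e+00,1.515707075279e+04
6.008333537379e-03,1.082914438607e+04,1.654605718177e-01,0.000000000000e+00,1.082930984664e+04
6.720880298405e-03,7.737092035498e+03,1.650175328048e-01,0.000000000000e+00,7.737257053031e+03
7.517930172232e-03,5.527915321065e+03,1.645256238686e-01,0.000000000000e+00,5.528079846689e+03
8.409504643011e-03,3.949526211743e+03,1.639799185994e-01,0.000000000000e+00,3.949690191662e+03
9.406813673533e-03,2.821815529229e+03,1.633751045676e-01,0.000000000000e+00,2.821978904334e+03
1.052239665057e-02,2.016100781234e+03,1.627054800322e-01,0.000000000000e+00,2.016263486714e+03
1.177028004535e-02,1.440442267749e+03,1.619649581402e-01,0.000000000000e+00,1.440604232707e+03
1.316615377149e-02,1.029151888651e+03,1.611470808675e-01,0.000000000000e+00,1.029313035732e+03
1.472756845772e-02,7.352975080139e+02,1.602450448335e-01,0.000000000000e+00,7.354577530588e+02
1.647415611586e-02,5.253475519540e+02,1.592517416060e-01,0.000000000000e+00,5.255068036956e+02
1.842787697838e-02,3.753447377912e+02,1.581598150728e-01,0.000000000000e+00,3.755028976063e+02
2.061329560933e-02,2.681723207114e+02,1.569617385958e-01,0.000000000000e+00,2.683292824500e+02
2.305788975997e-02,1.916009107226e+02,1.556499145027e-01,0.000000000000e+00,1.917565606371e+02
2.579239585260e-02,1.368929831847e+02,1.542167981016e-01,0.000000000000e+00,1.370471999828e+02
2.885119543648e-02,9.780584431734e+01,1.526550477928e-01,0.000000000000e+00,9.795849936513e+01
3.227274747451e-02,6.987928058901e+01,1.509577018283e-01,0.000000000000e+00,7.003023829083e+01
3.610007189639e-02,4.992660601951e+01,1.491183808802e-01,0.000000000000e+00,5.007572440039e+01
4.038129049762e-02,3.567103106410e+01,1.471315137238e-01,0.000000000000e+00,3.581816257782e+01
4.517023198549e-02,2.548585931675e+01,1.449925810716e-01,0.000000000000e+00,2.563085189782e+01
5.052710877934e-02,1.820886601079e+01,1.426983699495e-01,0.000000000000e+00,1.835156438074e+01
5.651927407456e-02,1.300967714207e+01,1.402472281520e-01,0.000000000000e+00,1.314992437022e+01
6.322206868922e-02,9.295015913703e+00,1.376393054763e-01,0.000000000000e+00,9.432655219179e+00
7.071976834082e-02,6.641004222667e+00,1.348767659572e-01,0.000000000000e+00,6.775880988624e+00
7.910664326351e-02,4.744794145049e+00,1.319639536207e-01,0.000000000000e+00,4.876758098670e+00
8.848814348856e-02,3.390010113539e+00,1.289074938109e-01,0.000000000000e+00,3.518917607350e+00
9.898222469091e-02,2.422058411509e+00,1.257163133728e-01,0.000000000000e+00,2.547774724882e+00
1.107208312719e-01,1.802253713245e+00,1.224015662260e-01,0.000000000000e+00,1.924655279472e+00
1.238515553255e-01,1.346542608294e+00,1.189764562860e-01,0.000000000000e+00,1.465519064580e+00
1.385394923460e-01,1.006061290398e+00,1.154559570940e-01,0.000000000000e+00,1.121517247492e+00
1.549693170106e-01,7.516729872527e-01,1.118564363686e-01,0.000000000000e+00,8.635294236213e-01
1.733476051344e-01,5.616084194506e-01,1.081952030665e-01,0.000000000000e+00,6.698036225171e-01
1.939054309945e-01,4.196028569486e-01,1.044900032442e-01,0.000000000000e+00,5.240928601929e-01
2.169012726769e-01,3.135042411597e-01,1.007584977076e-01,0.000000000000e+00,4.142627388674e-01
2.426242619795e-01,2.342332580781e-01,9.701775794480e-02,0.000000000000e+00,3.312510160229e-01
2.713978197296e-01,1.750063675286e-01,9.328381632243e-02,0.000000000000e+00,2.682901838511e-01
3.035837222257e-01,1.307552971282e-01,8.957130177920e-02,0.000000000000e+00,2.203265989074e-01
3.395866499305e-01,9.769332271872e-02,8.589318373672e-02,0.000000000000e+00,1.835865064554e-01
3.798592756079e-01,7.299121876951e-02,8.226063580347e-02,0.000000000000e+00,1.552518545730e-01
4.249079558778e-01,5.453514758333e-02,7.868301865098e-02,0.000000000000e+00,1.332181662343e-01
4.752990977496e-01,4.074576827538e-02,7.516796993720e-02,0.000000000000e+00,1.159137382126e-01
5.316662801827e-01,3.099776833898e-02,7.172157989519e-02,0.000000000000e+00,1.027193482342e-01
5.947182202147e-01,2.393583476957e-02,6.834862529396e-02,0.000000000000e+00,9.228446006353e-02
6.652476838175e-01,1.848278030386e-02,6.505283237590e-02,0.000000000000e+00,8.353561267976e-02
7.441414535185e-01,1.427205723520e-02,6.183714090361e-02,0.000000000000e+00,7.610919813881e-02
8.323914781137e-01,1.102062924956e-02,5.870394589511e-02,0.000000000000e+00,6.972457514467e-02
9.311073446592e-01,8.509944440666e-03,5.565529995474e-02,0.000000000000e+00,6.416524439541e-02
1.041530229554e+00,6.930139075730e-03,5.269306618584e-02,1.739037085657e-07,5.962337916528e-02
1.165048504124e+00,6.195406729277e-03,4.981901848075e-02,4.882254121243e-05,5.606324775124e-02
1.303215190924e+00,5.538570600350e-03,4.703489175502e-02,2.650149466797e-04,5.283847730205e-02
1.457767490233e+00,4.951372143187e-03,4.434238896765e-02,7.045342941208e-04,4.999829540496e-02
1.630648622253e+00,4.426428381861e-03,4.174315439867e-02,1.371580192390e-03,4.754116297292e-02
1.824032259651e+00,3.957139082488e-03,3.923872373407e-02,2.242231268018e-03,4.543809408457e-02
2.040349857623e+00,3.537603767028e-03,3.683046130296e-02,3.279287800003e-03,4.364735286999e-02
2.282321225119e+00,3.162547525275e-03,3.451949366932e-02,4.441359028445e-03,4.212340022304e-02
2.552988721599e+00,2.827254692242e-03,3.230664706362e-02,5.688158950598e-03,4.082206070646e-02
2.855755509295e+00,2.527509557065e-03,3.019239417192e-02,6.983347657341e-03,3.970325138632e-02
3.194428341915e+00,2.259543357938e-03,2.817681383866e-02,8.295820898724e-03,3.873217809532e-02
3.573265427806e+00,2.019986896639e-03,2.625956546748e-02,9.600050947209e-03,3.787960331133e-02
3.997029969344e+00,1.805828176857e-03,2.443987842818e-02,1.087587630842e-02,3.712158291345e-02
4.471050051729e+00,1.614374533694e-03,2.271655564515e-02,1.210799781086e-02,3.643892798970e-02
5.001285634179e+00,1.443218778199e-03,2.108798975240e-02,1.328534400305e-02,3.581655253364e-02
5.594403485815e+00,1.290208931244e-03,1.955218972043e-02,1.440040552815e-02,3.524280417982e-02
6.257861008420e+00,1.153421166221e-03,1.810681564244e-02,1.544859640124e-02,3.470883320991e-02
7.000000000000e+00,1.031135620340e-03,1.674921935363e-02,1.642767303828e-02,3.420802801225e-02
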