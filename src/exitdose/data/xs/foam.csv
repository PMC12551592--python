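# Photon mass attenuation coefficient table for material 'foam' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,8.141077680195e+02,2.275910810081e-01,0.000000000000e+00,8.143353591005e+02
1.118593076865e-03,5.816550692671e+02,2.274861656777e-01,0.000000000000e+00,5.818825554327e+02
1.251250471609e-03,4.155747345675e+02,2.273689537659e-01,0.000000000000e+00,4.158021035213e+02
1.399640114966e-03,2.969154214172e+02,2.272380282364e-01,0.000000000000e+00,2.971426594454e+02
1.565627742703e-03,2.121369759571e+02,2.270918072698e-01,0.000000000000e+00,2.123640677644e+02
1.751300353935e-03,1.515653729047e+02,2.269285368854e-01,0.000000000000e+00,1.517923014415e+02
1.958992451422e-03,1.082888174496e+02,2.267462657456e-01,0.000000000000e+00,1.085155637153e+02
2.191315393791e-03,7.736904386468e+01,2.265428306979e-01,0.000000000000e+00,7.759558669538e+01
2.451190228721e-03,5.527781251580e+01,2.263158320295e-01,0.000000000000e+00,5.550412834783e+01
2.741884419926e-03,3.949430423202e+01,2.260626153683e-01,0.000000000000e+00,3.972036684738e+01
3.067052929692e-03,2.821747091250e+01,2.257802431200e-01,0.000000000000e+00,2.844325115562e+01
3.430784173531e-03,2.016051884393e+01,2.254654724315e-01,0.000000000000e+00,2.038598431636e+01
3.837651424729e-03,1.440407332454e+01,2.251147273675e-01,0.000000000000e+00,1.462918805190e+01
4.292770315121e-03,1.029126928452e+01,2.247240717913e-01,0.000000000000e+00,1.051599335631e+01
4.801863155064e-03,7.352796747165e+00,2.242891818770e-01,0.000000000000e+00,7.577085929042e+00
5.371330881306e-03,5.253348106090e+00,2.238053183791e-01,0.000000000000e+00,5.477153424469e+00
6.008333537379e-03,3.753356344904e+00,2.232672997143e-01,0.000000000000e+00,3.976623644619e+00
6.720880298405e-03,2.681658166818e+00,2.226694767828e-01,0.000000000000e+00,2.904327643601e+00
7.517930172232e-03,1.915962637926e+00,2.220057103116e-01,0.000000000000e+00,2.137968348238e+00
8.409504643011e-03,1.368896630955e+00,2.212693527579e-01,0.000000000000e+00,1.590165983713e+00
9.406813673533e-03,9.780347221530e-01,2.204532356961e-01,0.000000000000e+00,1.198487957849e+00
1.052239665057e-02,6.987758579474e-01,2.195496653761e-01,0.000000000000e+00,9.183255233235e-01
1.177028004535e-02,4.992539514091e-01,2.185504283893e-01,0.000000000000e+00,7.178043797983e-01
1.316615377149e-02,3.567016592842e-01,2.174468104810e-01,0.000000000000e+00,5.741484697651e-01
1.472756845772e-02,2.548524120380e-01,2.162296313830e-01,0.000000000000e+00,4.710820434210e-01
1.647415611586e-02,1.820842438802e-01,2.148892992001e-01,0.000000000000e+00,3.969735430803e-01
1.842787697838e-02,1.300936161612e-01,2.134158878256e-01,0.000000000000e+00,3.435095039868e-01
2.061329560933e-02,9.294790480076e-02,2.117992410503e-01,0.000000000000e+00,3.047471458510e-01
2.305788975997e-02,6.640843157244e-02,2.100291068138e-01,0.000000000000e+00,2.764375383863e-01
2.579239585260e-02,4.744679068737e-02,2.080953045458e-01,0.000000000000e+00,2.555420952332e-01
2.885119543648e-02,3.389927895038e-02,2.059879277222e-01,0.000000000000e+00,2.398872066726e-01
3.227274747451e-02,2.421999668908e-02,2.036975823788e-01,0.000000000000e+00,2.279175790679e-01
3.610007189639e-02,1.730444592871e-02,2.012156604510e-01,0.000000000000e+00,2.185201063797e-01
4.038129049762e-02,1.236349669010e-02,1.985346443029e-01,0.000000000000e+00,2.108981409930e-01
4.517023198549e-02,8.833339769199e-03,1.956484357501e-01,0.000000000000e+00,2.044817755193e-01
5.052710877934e-02,6.311150755645e-03,1.925526993063e-01,0.000000000000e+00,1.988638500619e-01
5.651927407456e-02,4.509123944192e-03,1.892452055370e-01,0.000000000000e+00,1.937543294812e-01
6.322206868922e-02,3.221630972117e-03,1.857261565740e-01,0.000000000000e+00,1.889477875462e-01
7.071976834082e-02,2.301756671354e-03,1.819984724980e-01,0.000000000000e+00,1.843002291693e-01
7.910664326351e-02,1.644534653402e-03,1.780680150010e-01,0.000000000000e+00,1.797125496544e-01
8.848814348856e-02,1.174969648139e-03,1.739437241146e-01,0.000000000000e+00,1.751186937627e-01
9.898222469091e-02,8.394798316904e-04,1.696376454429e-01,0.000000000000e+00,1.704771252745e-01
1.107208312719e-01,6.103204367974e-04,1.651648297347e-01,0.000000000000e+00,1.657751501715e-01
1.238515553255e-01,4.444934528291e-04,1.605430939391e-01,0.000000000000e+00,1.609875873919e-01
1.385394923460e-01,3.237224628587e-04,1.557926428824e-01,0.000000000000e+00,1.561163653452e-01
1.549693170106e-01,2.357655327939e-04,1.509355626499e-01,0.000000000000e+00,1.511713281827e-01
1.733476051344e-01,1.717069226645e-04,1.459952094044e-01,0.000000000000e+00,1.461669163271e-01
1.939054309945e-01,1.250533430029e-04,1.409955291172e-01,0.000000000000e+00,1.411205824602e-01
2.169012726769e-01,9.107576295474e-05,1.359603527252e-01,0.000000000000e+00,1.360514284882e-01
2.426242619795e-01,6.633005245242e-05,1.309127159583e-01,0.000000000000e+00,1.309790460107e-01
2.713978197296e-01,4.830786831954e-05,1.258742523886e-01,0.000000000000e+00,1.259225602570e-01
3.035837222257e-01,3.518239636822e-05,1.208647018467e-01,0.000000000000e+00,1.208998842431e-01
3.395866499305e-01,2.562317663447e-05,1.159015648628e-01,0.000000000000e+00,1.159271880394e-01
3.798592756079e-01,1.866124151511e-05,1.109999187532e-01,0.000000000000e+00,1.110185799947e-01
4.249079558778e-01,1.359089653821e-05,1.061723945142e-01,0.000000000000e+00,1.061859854107e-01
4.752990977496e-01,9.898187780620e-06,1.014292981616e-01,0.000000000000e+00,1.014391963494e-01
5.316662801827e-01,7.228559959501e-06,9.677884766458e-02,0.000000000000e+00,9.678607622454e-02
5.947182202147e-01,5.290886954446e-06,9.222748864532e-02,0.000000000000e+00,9.223277953227e-02
6.652476838175e-01,3.872622951678e-06,8.778024917824e-02,0.000000000000e+00,8.778412180120e-02
7.441414535185e-01,2.834536044958e-06,8.344109608669e-02,0.000000000000e+00,8.344393062274e-02
8.323914781137e-01,2.074716629205e-06,7.921326113277e-02,0.000000000000e+00,7.921533584940e-02
9.311073446592e-01,1.518572830168e-06,7.509951403633e-02,0.000000000000e+00,7.510103260916e-02
1.041530229554e+00,1.195215894799e-06,7.110236881049e-02,1.290650900338e-08,7.110357693289e-02
1.165048504124e+00,1.068499277816e-06,6.722421908989e-02,3.623433754938e-06,6.722891102293e-02
1.303215190924e+00,9.552171383096e-07,6.346740591508e-02,1.966845804245e-05,6.348802959026e-02
1.457767490233e+00,8.539451549146e-07,5.983422720547e-02,5.228800630678e-05,5.988736915693e-02
1.630648622253e+00,7.634100126100e-07,5.632690170088e-02,1.017937584421e-04,5.642945886933e-02
1.824032259651e+00,6.824733930499e-07,5.294750160776e-02,1.664103559780e-04,5.311459443714e-02
2.040349857623e+00,6.101176622359e-07,4.969786790900e-02,2.433769691542e-04,4.994185499581e-02
2.282321225119e+00,5.454330755792e-07,4.657952075461e-02,3.296217243474e-04,4.690968791203e-02
2.552988721599e+00,4.876063394814e-07,4.359357503408e-02,4.221547390450e-04,4.401621737946e-02
2.855755509295e+00,4.359103856142e-07,4.074066857510e-02,5.182789956381e-04,4.125938348113e-02
3.194428341915e+00,3.896952293286e-07,3.802090776792e-02,6.156860483473e-04,3.863698351150e-02
3.573265427806e+00,3.483797972547e-07,3.543383302249e-02,7.124813208695e-04,3.614666272316e-02
3.997029969344e+00,3.114446213374e-07,3.297840447461e-02,8.071684994641e-04,3.378588441869e-02
4.471050051729e+00,2.784253074499e-07,3.065300682805e-02,8.986121345400e-04,3.155189738790e-02
5.001285634179e+00,2.489066964640e-07,2.845547115362e-02,9.859905427115e-04,2.944171060303e-02
5.594403485815e+00,2.225176443624e-07,2.638311081864e-02,1.068746406469e-03,2.745207974275e-02
6.257861008420e+00,1.989263557630e-07,2.443276842635e-02,1.146539370475e-03,2.557950672318e-02
7.000000000000e+00,1.778362121824e-07,2.260087062630e-02,1.219202923973e-03,2.382025138649e-02
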