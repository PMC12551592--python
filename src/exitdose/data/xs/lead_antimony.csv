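# Photon mass attenuation coefficient table for material 'lead_antimony' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,1.547896068603e+05,1.582058945539e-01,0.000000000000e+00,1.547897650662e+05
1.118593076865e-03,1.105924338729e+05,1.581329645269e-01,0.000000000000e+00,1.105925920059e+05
1.251250471609e-03,7.901490725395e+04,1.580514867498e-01,0.000000000000e+00,7.901506530544e+04
1.399640114966e-03,5.645373150502e+04,1.579604761952e-01,0.000000000000e+00,5.645388946550e+04
1.565627742703e-03,4.033446233884e+04,1.578588332893e-01,0.000000000000e+00,4.033462019767e+04
1.751300353935e-03,2.881773815108e+04,1.577453387837e-01,0.000000000000e+00,2.881789589642e+04
1.958992451422e-03,2.058939140350e+04,1.576186362407e-01,0.000000000000e+00,2.058954902214e+04
2.191315393791e-03,1.471048963469e+04,1.574772219834e-01,0.000000000000e+00,1.471064711191e+04
2.451190228721e-03,1.051019435453e+04,1.573194278939e-01,0.000000000000e+00,1.051035167396e+04
2.741884419926e-03,7.509212005392e+03,1.571434088328e-01,0.000000000000e+00,7.509369148801e+03
3.067052929692e-03,5.365102018082e+03,1.569471227835e-01,0.000000000000e+00,5.365258965204e+03
3.430784173531e-03,3.833201092705e+03,1.567283155344e-01,0.000000000000e+00,3.833357821021e+03
3.837651424729e-03,2.738704793981e+03,1.564845013376e-01,0.000000000000e+00,2.738861278482e+03
4.292770315121e-03,1.956720706056e+03,1.562129440577e-01,0.000000000000e+00,1.956876919000e+03
4.801863155064e-03,1.398017022471e+03,1.559106380639e-01,0.000000000000e+00,1.398172933109e+03
5.371330881306e-03,9.988403501176e+02,1.555742889540e-01,0.000000000000e+00,9.989959244065e+02
6.008333537379e-03,7.136408419831e+02,1.552002948424e-01,0.000000000000e+00,7.137960422779e+02
6.720880298405e-03,5.098745272819e+02,1.547847288577e-01,0.000000000000e+00,5.100293120107e+02
7.517930172232e-03,3.642897355041e+02,1.543233233937e-01,0.000000000000e+00,3.644440588275e+02
8.409504643011e-03,2.602738601222e+02,1.538114575289e-01,0.000000000000e+00,2.604276715797e+02
9.406813673533e-03,1.859577025116e+02,1.532441482598e-01,0.000000000000e+00,1.861109466599e+02
1.052239665057e-02,1.328610837338e+02,1.526160474127e-01,0.000000000000e+00,1.330136997812e+02
1.177028004535e-02,9.492517563131e+01,1.519214455827e-01,0.000000000000e+00,9.507709707689e+01
1.316615377149e-02,4.976263742068e+02,1.511542852104e-01,0.000000000000e+00,4.977775284920e+02
1.472756845772e-02,3.555388052156e+02,1.503081847957e-01,0.000000000000e+00,3.556891134004e+02
1.647415611586e-02,2.540215884168e+02,1.493764767030e-01,0.000000000000e+00,2.541709648935e+02
1.842787697838e-02,1.814906458458e+02,1.483522609758e-01,0.000000000000e+00,1.816389981067e+02
2.061329560933e-02,1.296695085438e+02,1.472284777056e-01,0.000000000000e+00,1.298167370215e+02
2.305788975997e-02,9.264489289585e+01,1.459980003551e-01,0.000000000000e+00,9.279089089620e+01
2.579239585260e-02,6.619193884572e+01,1.446537520817e-01,0.000000000000e+00,6.633659259780e+01
2.885119543648e-02,4.729211326394e+01,1.431888465412e-01,0.000000000000e+00,4.743530211048e+01
3.227274747451e-02,3.378876666813e+01,1.415967536864e-01,0.000000000000e+00,3.393036342181e+01
3.610007189639e-02,2.414103904770e+01,1.398714897741e-01,0.000000000000e+00,2.428091053748e+01
4.038129049762e-02,1.724803311192e+01,1.380078290536e-01,0.000000000000e+00,1.738604094097e+01
4.517023198549e-02,1.232319146007e+01,1.360015324802e-01,0.000000000000e+00,1.245919299255e+01
5.052710877934e-02,8.804542916640e+00,1.338495863177e-01,0.000000000000e+00,8.938392502958e+00
5.651927407456e-02,6.290576286358e+00,1.315504408143e-01,0.000000000000e+00,6.422126727172e+00
6.322206868922e-02,4.494424115953e+00,1.291042364785e-01,0.000000000000e+00,4.623528352431e+00
7.071976834082e-02,3.211128395003e+00,1.265130031522e-01,0.000000000000e+00,3.337641398155e+00
7.910664326351e-02,2.294252901633e+00,1.237808154867e-01,0.000000000000e+00,2.418033717120e+00
8.848814348856e-02,7.556949337837e+00,1.209138879858e-01,0.000000000000e+00,7.677863225822e+00
9.898222469091e-02,5.399208880220e+00,1.179205939373e-01,0.000000000000e+00,5.517129474157e+00
1.107208312719e-01,4.027267353333e+00,1.148113956017e-01,0.000000000000e+00,4.142078748935e+00
1.238515553255e-01,3.016955834505e+00,1.115986781142e-01,0.000000000000e+00,3.128554512619e+00
1.385394923460e-01,2.260099408909e+00,1.082964865009e-01,0.000000000000e+00,2.368395895410e+00
1.549693170106e-01,1.693114108120e+00,1.049201735114e-01,0.000000000000e+00,1.798034281631e+00
1.733476051344e-01,1.268367229021e+00,1.014859747672e-01,0.000000000000e+00,1.369853203788e+00
1.939054309945e-01,9.501756426960e-01,9.801053588433e-02,0.000000000000e+00,1.048186178580e+00
2.169012726769e-01,7.118080090039e-01,9.451042251519e-02,0.000000000000e+00,8.063184315191e-01
2.426242619795e-01,5.332390461213e-01,9.100164753790e-02,0.000000000000e+00,6.242406936592e-01
2.713978197296e-01,3.994671864734e-01,8.749924914565e-02,0.000000000000e+00,4.869664356191e-01
3.035837222257e-01,2.992542820126e-01,8.401694913068e-02,0.000000000000e+00,3.832712311433e-01
3.395866499305e-01,2.241814791740e-01,8.056691267556e-02,0.000000000000e+00,3.047483918495e-01
3.798592756079e-01,1.679419459688e-01,7.715962050875e-02,0.000000000000e+00,2.451015664776e-01
4.249079558778e-01,1.258110321222e-01,7.380385284278e-02,0.000000000000e+00,1.996148849650e-01
4.752990977496e-01,9.424934966132e-02,7.050677372133e-02,0.000000000000e+00,1.647561233826e-01
5.316662801827e-01,7.200644265835e-02,6.727409571964e-02,0.000000000000e+00,1.392805383780e-01
5.947182202147e-01,5.591198914646e-02,6.411029939735e-02,0.000000000000e+00,1.200222885438e-01
6.652476838175e-01,4.341491230044e-02,6.101887993105e-02,0.000000000000e+00,1.044337922315e-01
7.441414535185e-01,3.371112970092e-02,5.800259478748e-02,0.000000000000e+00,9.171372448839e-02
8.323914781137e-01,2.617628884661e-02,5.506369046860e-02,0.000000000000e+00,8.123997931522e-02
9.311073446592e-01,2.032559311227e-02,5.220409229596e-02,0.000000000000e+00,7.252968540823e-02
1.041530229554e+00,1.661102518646e-02,4.942554784108e-02,2.618362904016e-07,6.603683486383e-02
1.165048504124e+00,1.484992668918e-02,4.672972099653e-02,7.350914586281e-05,6.165315683157e-02
1.303215190924e+00,1.327553960087e-02,4.411823909504e-02,3.990169681365e-04,5.779279566404e-02
1.457767490233e+00,1.186806880486e-02,4.159269949444e-02,1.060774652564e-03,5.452154295187e-02
1.630648622253e+00,1.060981785988e-02,3.915464451229e-02,2.065105296061e-03,5.182956766823e-02
1.824032259651e+00,9.484966498829e-03,3.680551460606e-02,3.375991934171e-03,4.966647303906e-02
2.040349857623e+00,8.479371717028e-03,3.454658950228e-02,4.937425198081e-03,4.796338641739e-02
2.282321225119e+00,7.580389949127e-03,3.237892590622e-02,6.687085525322e-03,4.664640138066e-02
2.552988721599e+00,6.776718098752e-03,3.030329881348e-02,8.564316719423e-03,4.564433363165e-02
2.855755509295e+00,6.058251422176e-03,2.832015159865e-02,1.051440397829e-02,4.489280699912e-02
3.194428341915e+00,5.415956479149e-03,2.642955821701e-02,1.249051551501e-02,4.433603021117e-02
3.573265427806e+00,4.841757553452e-03,2.463119919273e-02,1.445421577501e-02,4.392717252119e-02
3.997029969344e+00,4.328435115139e-03,2.292435168266e-02,1.637514881626e-02,4.362793561406e-02
4.471050051729e+00,3.869535047787e-03,2.130789284237e-02,1.823027960204e-02,4.340770749220e-02
5.001285634179e+00,3.459287499466e-03,1.978031497927e-02,2.000293851785e-02,4.324254099659e-02
5.594403485815e+00,3.092534337117e-03,1.833975052840e-02,2.168181917952e-02,4.311410404504e-02
6.257861008420e+00,2.764664292207e-03,1.698400468154e-02,2.326001674705e-02,4.300868572080e-02
7.000000000000e+00,2.471554982225e-03,1.571059348765e-02,2.473415319172e-02,4.291630166160e-02
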