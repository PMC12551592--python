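# Photon mass attenuation coefficient table for material 'silicon_panel' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,2.611032080843e+04,1.989263045507e-01,0.000000000000e+00,2.611051973473e+04
1.118593076865e-03,1.865502462329e+04,1.988346031585e-01,0.000000000000e+00,1.865522345789e+04
1.251250471609e-03,1.332844380767e+04,1.987321539221e-01,0.000000000000e+00,1.332864253982e+04
1.399640114966e-03,9.522764934466e+03,1.986177182789e-01,0.000000000000e+00,9.522963552184e+03
1.565627742703e-03,6.803723923487e+03,1.984899136373e-01,0.000000000000e+00,6.803922413401e+03
1.751300353935e-03,4.861052388208e+03,1.983472069282e-01,0.000000000000e+00,4.861250735415e+03
1.958992451422e-03,3.473073068019e+03,1.981878925820e-01,0.000000000000e+00,3.473271255912e+03
2.191315393791e-03,2.481404348791e+03,1.980100798923e-01,0.000000000000e+00,2.481602358871e+03
2.451190228721e-03,1.772887417457e+03,1.978116713868e-01,0.000000000000e+00,1.773085229128e+03
2.741884419926e-03,1.266673767421e+03,1.975903470079e-01,0.000000000000e+00,1.266871357768e+03
3.067052929692e-03,9.049996165988e+02,1.973435391470e-01,0.000000000000e+00,9.051969601380e+02
3.430784173531e-03,6.465945116333e+02,1.970684133839e-01,0.000000000000e+00,6.467915800467e+02
3.837651424729e-03,4.619719774529e+02,1.967618441672e-01,0.000000000000e+00,4.621687392971e+02
4.292770315121e-03,3.300648306041e+02,1.964203911112e-01,0.000000000000e+00,3.302612509952e+02
4.801863155064e-03,2.358212136640e+02,1.960402749697e-01,0.000000000000e+00,2.360172539390e+02
5.371330881306e-03,1.684870354475e+02,1.956173533987e-01,0.000000000000e+00,1.686826528009e+02
6.008333537379e-03,1.203788271327e+02,1.951470974278e-01,0.000000000000e+00,1.205739742301e+02
6.720880298405e-03,8.600698554258e+01,1.946245694534e-01,0.000000000000e+00,8.620161011204e+01
7.517930172232e-03,6.144935731902e+01,1.940444034354e-01,0.000000000000e+00,6.164340172246e+01
8.409504643011e-03,4.390368399845e+01,1.934007890796e-01,0.000000000000e+00,4.409708478753e+01
9.406813673533e-03,3.136783772414e+01,1.926874608136e-01,0.000000000000e+00,3.156052518495e+01
1.052239665057e-02,2.241135945500e+01,1.918976939042e-01,0.000000000000e+00,2.260325714890e+01
1.177028004535e-02,1.601223001210e+01,1.910243094100e-01,0.000000000000e+00,1.620325432151e+01
1.316615377149e-02,1.144024799010e+01,1.900596906246e-01,0.000000000000e+00,1.163030768072e+01
1.472756845772e-02,8.173706846332e+00,1.889958135216e-01,0.000000000000e+00,8.362702659854e+00
1.647415611586e-02,5.839863232650e+00,1.878242942915e-01,0.000000000000e+00,6.027687526942e+00
1.842787697838e-02,4.172403441575e+00,1.865364570066e-01,0.000000000000e+00,4.358939898581e+00
2.061329560933e-02,2.981054484621e+00,1.851234246182e-01,0.000000000000e+00,3.166177909239e+00
2.305788975997e-02,2.129872138377e+00,1.835762362984e-01,0.000000000000e+00,2.313448374675e+00
2.579239585260e-02,1.521728418329e+00,1.818859937054e-01,0.000000000000e+00,1.703614412034e+00
2.885119543648e-02,1.087228353959e+00,1.800440380279e-01,0.000000000000e+00,1.267272391987e+00
3.227274747451e-02,7.767913639608e-01,1.780421584583e-01,0.000000000000e+00,9.548335224191e-01
3.610007189639e-02,5.549936413331e-01,1.758728311055e-01,0.000000000000e+00,7.308664724385e-01
4.038129049762e-02,3.965259607800e-01,1.735294851693e-01,0.000000000000e+00,5.700554459493e-01
4.517023198549e-02,2.833056558897e-01,1.710067905232e-01,0.000000000000e+00,4.543124464129e-01
5.052710877934e-02,2.024132152690e-01,1.683009577291e-01,0.000000000000e+00,3.707141729980e-01
5.651927407456e-02,1.446180436704e-01,1.654100381468e-01,0.000000000000e+00,3.100280818172e-01
6.322206868922e-02,1.033251634645e-01,1.623342084498e-01,0.000000000000e+00,2.656593719143e-01
7.071976834082e-02,7.382266509776e-02,1.590760209387e-01,0.000000000000e+00,2.328986860364e-01
7.910664326351e-02,5.274403349003e-02,1.556405990337e-01,0.000000000000e+00,2.083846325237e-01
8.848814348856e-02,3.768399671177e-02,1.520357567820e-01,0.000000000000e+00,1.897197534938e-01
9.898222469091e-02,2.692406162757e-02,1.482720226608e-01,0.000000000000e+00,1.751960842884e-01
1.107208312719e-01,1.973792688982e-02,1.443625517984e-01,0.000000000000e+00,1.641004786882e-01
1.238515553255e-01,1.450725510151e-02,1.403229171239e-01,0.000000000000e+00,1.548301722254e-01
1.385394923460e-01,1.066274344591e-02,1.361707786944e-01,0.000000000000e+00,1.468335221403e-01
1.549693170106e-01,7.837050978819e-03,1.319254408838e-01,0.000000000000e+00,1.397624918626e-01
1.733476051344e-01,5.760184361199e-03,1.276073181791e-01,0.000000000000e+00,1.333675025403e-01
1.939054309945e-01,4.233700146226e-03,1.232373405901e-01,0.000000000000e+00,1.274710407363e-01
2.169012726769e-01,3.111743618641e-03,1.188363375807e-01,0.000000000000e+00,1.219480811994e-01
2.426242619795e-01,2.287112458066e-03,1.144244435631e-01,0.000000000000e+00,1.167115560212e-01
2.713978197296e-01,1.681013617094e-03,1.100205673915e-01,0.000000000000e+00,1.117015810086e-01
3.035837222257e-01,1.235534689556e-03,1.056419626924e-01,0.000000000000e+00,1.068774973820e-01
3.395866499305e-01,9.081104124161e-04,1.013039258290e-01,0.000000000000e+00,1.022120362415e-01
3.798592756079e-01,6.674555786327e-04,9.701963515087e-02,0.000000000000e+00,9.768709072951e-02
4.249079558778e-01,4.905757530769e-04,9.280013079799e-02,0.000000000000e+00,9.329070655107e-02
4.752990977496e-01,3.605701670813e-04,8.865442075797e-02,0.000000000000e+00,8.901499092505e-02
5.316662801827e-01,2.672055951551e-04,8.458968795841e-02,0.000000000000e+00,8.485689355357e-02
5.947182202147e-01,1.993647511076e-04,8.061156620436e-02,0.000000000000e+00,8.081093095547e-02
6.652476838175e-01,1.487480228890e-04,7.672445029139e-02,0.000000000000e+00,7.687319831428e-02
7.441414535185e-01,1.109823787327e-04,7.293180742701e-02,0.000000000000e+00,7.304278980574e-02
8.323914781137e-01,8.280505616107e-05,6.923646233743e-02,0.000000000000e+00,6.931926739359e-02
9.311073446592e-01,6.178167565098e-05,6.564083590020e-02,0.000000000000e+00,6.570261757585e-02
1.041530229554e+00,4.922360189280e-05,6.214712549201e-02,4.002189603493e-08,6.219638911580e-02
1.165048504124e+00,4.400492271128e-05,5.875742327260e-02,1.123593444142e-05,5.881266412975e-02
1.303215190924e+00,3.933952714478e-05,5.547377543173e-02,6.099007738934e-05,5.557410503626e-02
1.457767490233e+00,3.516875614414e-05,5.229819046911e-02,1.621402930673e-04,5.249549951832e-02
1.630648622253e+00,3.144016968415e-05,4.923260767740e-02,3.156530721289e-04,4.957970091921e-02
1.824032259651e+00,2.810688742351e-05,4.627883827157e-02,5.160231914258e-04,4.682296835042e-02
2.040349857623e+00,2.512699926795e-05,4.343849136529e-02,7.546895720785e-04,4.421830793663e-02
2.282321225119e+00,2.246303842536e-05,4.071289564782e-02,1.022126616828e-03,4.175748530308e-02
2.552988721599e+00,2.008151032753e-05,3.810302558989e-02,1.309062975301e-03,3.943217007552e-02
2.855755509295e+00,1.795247149554e-05,3.560943868570e-02,1.607135444223e-03,3.723452660142e-02
3.194428341915e+00,1.604915305382e-05,3.323222792578e-02,1.909185745787e-03,3.515746282462e-02
3.573265427806e+00,1.434762415910e-05,3.097099160481e-02,2.209338973320e-03,3.319467820229e-02
3.997029969344e+00,1.282649111267e-05,2.882482082801e-02,2.502955195690e-03,3.134060251482e-02
4.471050051729e+00,1.146662837269e-05,2.679230374347e-02,2.786513488262e-03,2.959028386010e-02
5.001285634179e+00,1.025093808450e-05,2.487154459554e-02,3.057465886515e-03,2.793926142014e-02
5.594403485815e+00,9.164135105530e-06,2.306019512916e-02,3.314084200168e-03,2.638344346443e-02
6.257861008420e+00,8.192554821827e-06,2.135549561726e-02,3.555313018655e-03,2.491900119074e-02
7.000000000000e+00,7.323981339837e-06,1.975432276786e-02,3.780636007456e-03,2.354228275665e-02
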