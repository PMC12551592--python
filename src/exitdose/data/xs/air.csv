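# Photon mass attenuation coefficient table for material 'air' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,2.107872086627e+03,1.994579584687e-01,0.000000000000e+00,2.108071544586e+03
1.118593076865e-03,1.506010055077e+03,1.993660119938e-01,0.000000000000e+00,1.506209421089e+03
1.251250471609e-03,1.075998064769e+03,1.992632889498e-01,0.000000000000e+00,1.076197328058e+03
1.399640114966e-03,7.687676662477e+02,1.991485474639e-01,0.000000000000e+00,7.689668147952e+02
1.565627742703e-03,5.492609550323e+02,1.990204012494e-01,0.000000000000e+00,5.494599754335e+02
1.751300353935e-03,3.924301319740e+02,1.988773131398e-01,0.000000000000e+00,3.926290092872e+02
1.958992451422e-03,2.803793116372e+02,1.987175730073e-01,0.000000000000e+00,2.805780292103e+02
2.191315393791e-03,2.003224319160e+02,1.985392850923e-01,0.000000000000e+00,2.005209712011e+02
2.451190228721e-03,1.431242429922e+02,1.983403463168e-01,0.000000000000e+00,1.433225833385e+02
2.741884419926e-03,1.022578886257e+02,1.981184304224e-01,0.000000000000e+00,1.024560070561e+02
3.067052929692e-03,7.306012990929e+01,1.978709629385e-01,0.000000000000e+00,7.325800087223e+01
3.430784173531e-03,5.219922544951e+01,1.975951018695e-01,0.000000000000e+00,5.239682055138e+01
3.837651424729e-03,3.729474805084e+01,1.972877133106e-01,0.000000000000e+00,3.749203576416e+01
4.292770315121e-03,2.664595537957e+01,1.969453476812e-01,0.000000000000e+00,2.684290072725e+01
4.801863155064e-03,1.903771912126e+01,1.965642156347e-01,0.000000000000e+00,1.923428333690e+01
5.371330881306e-03,1.360186730696e+01,1.961401637561e-01,0.000000000000e+00,1.379800747071e+01
6.008333537379e-03,9.718117651470e+00,1.956686509708e-01,0.000000000000e+00,9.913786302441e+00
6.720880298405e-03,6.943297457366e+00,1.951447264791e-01,0.000000000000e+00,7.138442183845e+00
7.517930172232e-03,4.960773403908e+00,1.945630098992e-01,0.000000000000e+00,5.155336413807e+00
8.409504643011e-03,3.544320679912e+00,1.939176754085e-01,0.000000000000e+00,3.738238355320e+00
9.406813673533e-03,2.532308585624e+00,1.932024406888e-01,0.000000000000e+00,2.725511026312e+00
1.052239665057e-02,1.809256935798e+00,1.924105630345e-01,0.000000000000e+00,2.001667498833e+00
1.177028004535e-02,1.292658674507e+00,1.915348443177e-01,0.000000000000e+00,1.484193518824e+00
1.316615377149e-02,9.235650369581e-01,1.905676474753e-01,0.000000000000e+00,1.114132684433e+00
1.472756845772e-02,6.598589359383e-01,1.895009270358e-01,0.000000000000e+00,8.493598629741e-01
1.647415611586e-02,4.714490024133e-01,1.883262767829e-01,0.000000000000e+00,6.597752791961e-01
1.842787697838e-02,3.368358747168e-01,1.870349976016e-01,0.000000000000e+00,5.238708723184e-01
2.061329560933e-02,2.406589173282e-01,1.856181887181e-01,0.000000000000e+00,4.262771060463e-01
2.305788975997e-02,1.719434265672e-01,1.840668653558e-01,0.000000000000e+00,3.560102919230e-01
2.579239585260e-02,1.228483127403e-01,1.823721053909e-01,0.000000000000e+00,3.052204181312e-01
2.885119543648e-02,8.777135738445e-02,1.805252268705e-01,0.000000000000e+00,2.682965842549e-01
3.227274747451e-02,6.270994696846e-02,1.785179970425e-01,0.000000000000e+00,2.412279440110e-01
3.610007189639e-02,4.480433669907e-02,1.763428719075e-01,0.000000000000e+00,2.211472086065e-01
4.038129049762e-02,3.201132649743e-02,1.739932631040e-01,0.000000000000e+00,2.060045896015e-01
4.517023198549e-02,2.287111247751e-02,1.714638262601e-01,0.000000000000e+00,1.943349387377e-01
5.052710877934e-02,1.634070946735e-02,1.687507618100e-01,0.000000000000e+00,1.850914712773e-01
5.651927407456e-02,1.167493650162e-02,1.658521159055e-01,0.000000000000e+00,1.775270524071e-01
6.322206868922e-02,8.341384600789e-03,1.627680656923e-01,0.000000000000e+00,1.711094502931e-01
7.071976834082e-02,5.959663853298e-03,1.595011702923e-01,0.000000000000e+00,1.654608341456e-01
7.910664326351e-02,4.257997316291e-03,1.560565668187e-01,0.000000000000e+00,1.603145641350e-01
8.848814348856e-02,3.042208686905e-03,1.524420902026e-01,0.000000000000e+00,1.554842988895e-01
9.898222469091e-02,2.173564943142e-03,1.486682970598e-01,0.000000000000e+00,1.508418620030e-01
1.107208312719e-01,1.583367415613e-03,1.447483776772e-01,0.000000000000e+00,1.463317450929e-01
1.238515553255e-01,1.155679242017e-03,1.406979466045e-01,0.000000000000e+00,1.418536258466e-01
1.385394923460e-01,8.435156213386e-04,1.365347110973e-01,0.000000000000e+00,1.373782267187e-01
1.549693170106e-01,6.156716484198e-04,1.322780271227e-01,0.000000000000e+00,1.328936987711e-01
1.733476051344e-01,4.493713578839e-04,1.279483637278e-01,0.000000000000e+00,1.283977350857e-01
1.939054309945e-01,3.279909258938e-04,1.235667068603e-01,0.000000000000e+00,1.238946977862e-01
2.169012726769e-01,2.393968755049e-04,1.191539416534e-01,0.000000000000e+00,1.193933385289e-01
2.426242619795e-01,1.747331616542e-04,1.147302563307e-01,0.000000000000e+00,1.149049894924e-01
2.713978197296e-01,1.275358851678e-04,1.103146102827e-01,0.000000000000e+00,1.104421461678e-01
3.035837222257e-01,9.308713729666e-05,1.059243032482e-01,0.000000000000e+00,1.060173903855e-01
3.395866499305e-01,6.794338140723e-05,1.015746724716e-01,0.000000000000e+00,1.016426158530e-01
3.798592756079e-01,4.959122632463e-05,9.727893152332e-02,0.000000000000e+00,9.732852274965e-02
4.249079558778e-01,3.619618068395e-05,9.304815004937e-02,0.000000000000e+00,9.308434623005e-02
4.752990977496e-01,2.641927257684e-05,8.889136011224e-02,0.000000000000e+00,8.891777938482e-02
5.316662801827e-01,1.936144209994e-05,8.481576383676e-02,0.000000000000e+00,8.483512527886e-02
5.947182202147e-01,1.423659585011e-05,8.082701008499e-02,0.000000000000e+00,8.084124668084e-02
6.652476838175e-01,1.046828476067e-05,7.692950539810e-02,0.000000000000e+00,7.693997368286e-02
7.441414535185e-01,7.697431220232e-06,7.312672625011e-02,0.000000000000e+00,7.313442368133e-02
8.323914781137e-01,5.660007731396e-06,6.942150491667e-02,0.000000000000e+00,6.942716492440e-02
9.311073446592e-01,4.161876137646e-06,6.581626874539e-02,0.000000000000e+00,6.582043062153e-02
1.041530229554e+00,3.285270905867e-06,6.231322098571e-02,1.821113935578e-08,6.231652446775e-02
1.165048504124e+00,2.936966957703e-06,5.891445938890e-02,5.112680511852e-06,5.892250903637e-02
1.303215190924e+00,2.625590143947e-06,5.562203561342e-02,2.775227834503e-05,5.565241348191e-02
1.457767490233e+00,2.347225455129e-06,5.243796352694e-02,7.377860033566e-05,5.251408935273e-02
1.630648622253e+00,2.098372950517e-06,4.936418760508e-02,1.436314281463e-04,4.950991740618e-02
1.824032259651e+00,1.875903752595e-06,4.640252390352e-02,2.348057233887e-04,4.663920553066e-02
2.040349857623e+00,1.677020706988e-06,4.355458583645e-02,3.434059434736e-04,4.389966880064e-02
2.282321225119e+00,1.499223213224e-06,4.082170564424e-02,4.650976615917e-04,4.128830252905e-02
2.552988721599e+00,1.340275784137e-06,3.820486040199e-02,5.956621407415e-04,3.880186281851e-02
2.855755509295e+00,1.198179938583e-06,3.570460909386e-02,7.312938775519e-04,3.643710115135e-02
3.194428341915e+00,1.071149074104e-06,3.332104495891e-02,8.687356451639e-04,3.419085175315e-02
3.573265427806e+00,9.575860035772e-07,3.105376521823e-02,1.005314188318e-03,3.206003699255e-02
3.997029969344e+00,8.560628734278e-07,2.890185854791e-02,1.138918201931e-03,3.004163281272e-02
4.471050051729e+00,7.653032109114e-07,2.686390932268e-02,1.267945561780e-03,2.813262018767e-02
5.001285634179e+00,6.841658747402e-07,2.493801672029e-02,1.391236869095e-03,2.632993775526e-02
5.594403485815e+00,6.116307072612e-07,2.312182620967e-02,1.508005746489e-03,2.463044358687e-02
6.257861008420e+00,5.467857077889e-07,2.141257068806e-02,1.617771951125e-03,2.303088942490e-02
7.000000000000e+00,4.888155658191e-07,1.980711851612e-02,1.720300535616e-03,2.152790786730e-02
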