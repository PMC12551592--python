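# Photon mass attenuation coefficient table for material 'copper' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,2.944368849629e+05,1.821161190722e-01,0.000000000000e+00,2.944370670790e+05
1.118593076865e-03,2.103661375625e+05,1.820321668685e-01,0.000000000000e+00,2.103663195946e+05
1.251250471609e-03,1.503001631013e+05,1.819383750626e-01,0.000000000000e+00,1.503003450396e+05
1.399640114966e-03,1.073848637904e+05,1.818336097563e-01,0.000000000000e+00,1.073850456240e+05
1.565627742703e-03,7.672319665763e+04,1.817166051933e-01,0.000000000000e+00,7.672337837423e+04
1.751300353935e-03,5.481637446458e+04,1.815859578559e-01,0.000000000000e+00,5.481655605054e+04
1.958992451422e-03,3.916462087536e+04,1.814401063030e-01,0.000000000000e+00,3.916480231546e+04
2.191315393791e-03,2.798192225028e+04,1.812773196014e-01,0.000000000000e+00,2.798210352760e+04
2.451190228721e-03,1.999222653815e+04,1.810956775250e-01,0.000000000000e+00,1.999240763383e+04
2.741884419926e-03,1.428383362579e+04,1.808930560716e-01,0.000000000000e+00,1.428401451884e+04
3.067052929692e-03,1.020536170195e+04,1.806671046074e-01,0.000000000000e+00,1.020554236905e+04
3.430784173531e-03,7.291418410223e+03,1.804152282336e-01,0.000000000000e+00,7.291598825451e+03
3.837651424729e-03,5.209495163976e+03,1.801345655224e-01,0.000000000000e+00,5.209675298542e+03
4.292770315121e-03,3.722024760703e+03,1.798219668164e-01,0.000000000000e+00,3.722204582670e+03
4.801863155064e-03,2.659272709394e+03,1.794739722330e-01,0.000000000000e+00,2.659452183367e+03
5.371330881306e-03,1.899968914123e+03,1.790867894752e-01,0.000000000000e+00,1.900148000912e+03
6.008333537379e-03,1.357469605084e+03,1.786562722915e-01,0.000000000000e+00,1.357648261356e+03
6.720880298405e-03,9.698704621059e+02,1.781779003285e-01,0.000000000000e+00,9.700486400062e+02
7.517930172232e-03,6.929427441635e+02,1.776467610011e-01,0.000000000000e+00,6.931203909245e+02
8.409504643011e-03,4.950863702419e+02,1.770575350115e-01,0.000000000000e+00,4.952634277770e+02
9.406813673533e-03,3.537240501670e+02,1.764044862569e-01,0.000000000000e+00,3.539004546532e+02
1.052239665057e-02,2.527250015091e+02,1.756814582750e-01,0.000000000000e+00,2.529006829674e+02
1.177028004535e-02,1.805642742065e+02,1.748818787781e-01,0.000000000000e+00,1.807391560852e+02
1.316615377149e-02,1.290076443764e+02,1.739987747060e-01,0.000000000000e+00,1.291816431511e+02
1.472756845772e-02,9.217201121699e+01,1.730248000997e-01,0.000000000000e+00,9.234503601709e+01
1.647415611586e-02,6.585407936756e+01,1.719522796198e-01,0.000000000000e+00,6.602603164718e+01
1.842787697838e-02,4.705072301329e+01,1.707732704946e-01,0.000000000000e+00,4.722149628379e+01
2.061329560933e-02,3.361630072630e+01,1.694796458265e-01,0.000000000000e+00,3.378578037213e+01
2.305788975997e-02,2.401781741381e+01,1.680632020188e-01,0.000000000000e+00,2.418588061583e+01
2.579239585260e-02,1.715999502801e+01,1.665157926803e-01,0.000000000000e+00,1.732651082069e+01
2.885119543648e-02,1.226029094516e+01,1.648294907091e-01,0.000000000000e+00,1.242512043587e+01
3.227274747451e-02,8.759602424986e+00,1.629967791484e-01,0.000000000000e+00,8.922599204134e+00
3.610007189639e-02,6.258467681314e+00,1.610107699106e-01,0.000000000000e+00,6.419478451225e+00
4.038129049762e-02,4.471483500933e+00,1.588654474581e-01,0.000000000000e+00,4.630348948391e+00
4.517023198549e-02,3.194738028098e+00,1.565559320846e-01,0.000000000000e+00,3.351293960182e+00
5.052710877934e-02,2.282542486413e+00,1.540787545769e-01,0.000000000000e+00,2.436621240990e+00
5.651927407456e-02,1.630806706671e+00,1.514321309639e-01,0.000000000000e+00,1.782238837635e+00
6.322206868922e-02,1.165161450600e+00,1.486162229893e-01,0.000000000000e+00,1.313777673589e+00
7.071976834082e-02,8.324721749120e-01,1.456333672725e-01,0.000000000000e+00,9.781055421845e-01
7.910664326351e-02,5.947758756058e-01,1.424882542815e-01,0.000000000000e+00,7.372641298873e-01
8.848814348856e-02,4.249491488891e-01,1.391880377403e-01,0.000000000000e+00,5.641371866294e-01
9.898222469091e-02,3.036131533708e-01,1.357423564217e-01,0.000000000000e+00,4.393555097925e-01
1.107208312719e-01,2.241747223141e-01,1.321632537852e-01,0.000000000000e+00,3.563379760993e-01
1.238515553255e-01,1.660685348546e-01,1.284649867760e-01,0.000000000000e+00,2.945335216305e-01
1.385394923460e-01,1.230234969583e-01,1.246637230953e-01,0.000000000000e+00,2.476872200536e-01
1.549693170106e-01,9.113575197797e-02,1.207771358088e-01,0.000000000000e+00,2.119128877867e-01
1.733476051344e-01,6.751332464078e-02,1.168239142857e-01,0.000000000000e+00,1.843372389265e-01
1.939054309945e-01,5.001384094744e-02,1.128232198539e-01,0.000000000000e+00,1.628370608014e-01
2.169012726769e-01,3.705023118954e-02,1.087941217922e-01,0.000000000000e+00,1.458443529817e-01
2.426242619795e-01,2.744679483108e-02,1.047550530624e-01,0.000000000000e+00,1.322018478935e-01
2.713978197296e-01,2.033257343646e-02,1.007233246338e-01,0.000000000000e+00,1.210558980703e-01
3.035837222257e-01,1.506236138294e-02,9.671473212240e-02,0.000000000000e+00,1.117770935053e-01
3.395866499305e-01,1.115819063137e-02,9.274327927839e-02,0.000000000000e+00,1.039014699098e-01
3.798592756079e-01,8.265982670351e-03,8.882103082037e-02,0.000000000000e+00,9.708701349072e-02
4.249079558778e-01,6.123436295707e-03,8.495809394588e-02,0.000000000000e+00,9.108153024159e-02
4.752990977496e-01,4.536238891726e-03,8.116271542622e-02,0.000000000000e+00,8.569895431794e-02
5.316662801827e-01,3.404215509667e-03,7.744147119864e-02,0.000000000000e+00,8.084568670831e-02
5.947182202147e-01,2.582112894638e-03,7.379951898583e-02,0.000000000000e+00,7.638163188047e-02
6.652476838175e-01,1.958544334730e-03,7.024088220297e-02,0.000000000000e+00,7.219942653770e-02
7.441414535185e-01,1.485564755541e-03,6.676873506260e-02,0.000000000000e+00,6.825429981815e-02
8.323914781137e-01,1.126807600814e-03,6.338566358864e-02,0.000000000000e+00,6.451247118946e-02
9.311073446592e-01,8.546886727872e-04,6.009388408336e-02,0.000000000000e+00,6.094857275615e-02
1.041530229554e+00,6.881435474329e-04,5.689540823504e-02,8.779661785887e-08,5.758363957909e-02
1.165048504124e+00,6.151866676680e-04,5.379215140631e-02,2.464843348701e-05,5.443198650746e-02
1.303215190924e+00,5.499646657857e-04,5.078598687453e-02,1.337948235401e-04,5.146974636385e-02
1.457767490233e+00,4.916574911470e-04,4.787875341195e-02,3.556895289902e-04,4.872610043209e-02
1.630648622253e+00,4.395320347638e-04,4.507222643211e-02,6.924527544995e-04,4.620421122138e-02
1.824032259651e+00,3.929329117571e-04,4.236806409401e-02,1.132007611643e-03,4.389300461741e-02
2.040349857623e+00,3.512742210586e-04,3.976773953382e-02,1.655573536647e-03,4.177458729153e-02
2.282321225119e+00,3.140321787465e-04,3.727246916048e-02,2.242254087681e-03,3.982875542690e-02
2.552988721599e+00,2.807385323953e-04,3.488314509745e-02,2.871710568020e-03,3.803559419786e-02
2.855755509295e+00,2.509746736339e-04,3.260027772812e-02,3.525596496497e-03,3.637684889825e-02
3.194428341915e+00,2.243663748907e-04,3.042395218489e-02,4.188208654536e-03,3.483652721431e-02
3.573265427806e+00,2.005790841470e-04,2.835380070839e-02,4.846659173568e-03,3.340103896610e-02
3.997029969344e+00,1.793137185412e-04,2.638899120962e-02,5.490769368899e-03,3.205907429706e-02
4.471050051729e+00,1.603029039334e-04,2.452823114462e-02,6.112815336735e-03,3.080134938529e-02
5.001285634179e+00,1.433076131516e-04,2.276978495781e-02,6.707207570091e-03,2.962030014105e-02
5.594403485815e+00,1.281141606502e-04,2.111150283245e-02,7.270154912709e-03,2.850977190581e-02
6.257861008420e+00,1.145315157942e-04,1.955085825107e-02,7.799342095014e-03,2.746473186188e-02
7.000000000000e+00,1.023889009891e-04,1.808499185418e-02,8.293636426430e-03,2.648101718160e-02
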