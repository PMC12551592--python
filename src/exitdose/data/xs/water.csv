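# Photon mass attenuation coefficient table for material 'water' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,2.731174909510e+03,2.215142882548e-01,0.000000000000e+00,2.731396423799e+03
1.118593076865e-03,1.951340834195e+03,2.214121742148e-01,0.000000000000e+00,1.951562246369e+03
1.251250471609e-03,1.394173268778e+03,2.212980919182e-01,0.000000000000e+00,1.394394566870e+03
1.399640114966e-03,9.960941058136e+02,2.211706621641e-01,0.000000000000e+00,9.963152764758e+02
1.565627742703e-03,7.116787345280e+02,2.210283453686e-01,0.000000000000e+00,7.118997628734e+02
1.751300353935e-03,5.084726615922e+02,2.208694343830e-01,0.000000000000e+00,5.086935310266e+02
1.958992451422e-03,3.632881453991e+02,2.206920299715e-01,0.000000000000e+00,3.635088374291e+02
2.191315393791e-03,2.595582546646e+02,2.204940267387e-01,0.000000000000e+00,2.597787486913e+02
2.451190228721e-03,1.854464243267e+02,2.202730890453e-01,0.000000000000e+00,1.856666974157e+02
2.741884419926e-03,1.324957911278e+02,2.200266333923e-01,0.000000000000e+00,1.327158177612e+02
3.067052929692e-03,9.466418525096e+01,2.197518006206e-01,0.000000000000e+00,9.488393705158e+01
3.430784173531e-03,6.763466139527e+01,2.194454344629e-01,0.000000000000e+00,6.785410682973e+01
3.837651424729e-03,4.832289434410e+01,2.191040544630e-01,0.000000000000e+00,4.854199839857e+01
4.292770315121e-03,3.452522818359e+01,2.187238295810e-01,0.000000000000e+00,3.474395201317e+01
4.801863155064e-03,2.466721824733e+01,2.183005514393e-01,0.000000000000e+00,2.488551879877e+01
5.371330881306e-03,1.762397203651e+01,2.178296073326e-01,0.000000000000e+00,1.784180164384e+01
6.008333537379e-03,1.259178830905e+01,2.173059540283e-01,0.000000000000e+00,1.280909426308e+01
6.720880298405e-03,8.996447139810e+00,2.167240932603e-01,0.000000000000e+00,9.213171233071e+00
7.517930172232e-03,6.427685976998e+00,2.160780496773e-01,0.000000000000e+00,6.643764026675e+00
8.409504643011e-03,4.592384791110e+00,2.153613532290e-01,0.000000000000e+00,4.807746144339e+00
9.406813673533e-03,3.281118297486e+00,2.145670268905e-01,0.000000000000e+00,3.495685324376e+00
1.052239665057e-02,2.344258543608e+00,2.136875823382e-01,0.000000000000e+00,2.557946125947e+00
1.177028004535e-02,1.674900939564e+00,2.127150254658e-01,0.000000000000e+00,1.887615965030e+00
1.316615377149e-02,1.196665429674e+00,2.116408746934e-01,0.000000000000e+00,1.408306304367e+00
1.472756845772e-02,8.549808031922e-01,2.104561948704e-01,0.000000000000e+00,1.065436998063e+00
1.647415611586e-02,6.108576012148e-01,2.091516502099e-01,0.000000000000e+00,8.200092514247e-01
1.842787697838e-02,4.364390493550e-01,2.077175796369e-01,0.000000000000e+00,6.441566289919e-01
2.061329560933e-02,3.118223353905e-01,2.061440981182e-01,0.000000000000e+00,5.179664335087e-01
2.305788975997e-02,2.227875094864e-01,2.044212273283e-01,0.000000000000e+00,4.272087368147e-01
2.579239585260e-02,1.591748529527e-01,2.025390585231e-01,0.000000000000e+00,3.617139114758e-01
2.885119543648e-02,1.137255579135e-01,2.004879496875e-01,0.000000000000e+00,3.142135076010e-01
3.227274747451e-02,8.125342843314e-02,1.982587576807e-01,0.000000000000e+00,2.795121861139e-01
3.610007189639e-02,5.805308633578e-02,1.958431042776e-01,0.000000000000e+00,2.538961906134e-01
4.038129049762e-02,4.147715238727e-02,1.932336725669e-01,0.000000000000e+00,2.347108249542e-01
4.517023198549e-02,2.963415519730e-02,1.904245271888e-01,0.000000000000e+00,2.200586823861e-01
5.052710877934e-02,2.117269638133e-02,1.874114484164e-01,0.000000000000e+00,2.085841447977e-01
5.651927407456e-02,1.512724317839e-02,1.841922663423e-01,0.000000000000e+00,1.993195095207e-01
6.322206868922e-02,1.080795199898e-02,1.807671777012e-01,0.000000000000e+00,1.915751297002e-01
7.071976834082e-02,7.721950723911e-03,1.771390246062e-01,0.000000000000e+00,1.848609753302e-01
7.910664326351e-02,5.517097317619e-03,1.733135122395e-01,0.000000000000e+00,1.788306095571e-01
8.848814348856e-02,3.941797079568e-03,1.692993419292e-01,0.000000000000e+00,1.732411390088e-01
9.898222469091e-02,2.816293300984e-03,1.651082376561e-01,0.000000000000e+00,1.679245309571e-01
1.107208312719e-01,2.053300787500e-03,1.607548483067e-01,0.000000000000e+00,1.628081490942e-01
1.238515553255e-01,1.500065844774e-03,1.562565151087e-01,0.000000000000e+00,1.577565809534e-01
1.385394923460e-01,1.095892804018e-03,1.516329034098e-01,0.000000000000e+00,1.527287962138e-01
1.549693170106e-01,8.006188874445e-04,1.469055095860e-01,0.000000000000e+00,1.477061284735e-01
1.733476051344e-01,5.849026526282e-04,1.420970661793e-01,0.000000000000e+00,1.426819688320e-01
1.939054309945e-01,4.273083249666e-04,1.372308797918e-01,0.000000000000e+00,1.376581881168e-01
2.169012726769e-01,3.121757187516e-04,1.323301450628e-01,0.000000000000e+00,1.326423207816e-01
2.426242619795e-01,2.280640802290e-04,1.274172826569e-01,0.000000000000e+00,1.276453467372e-01
2.713978197296e-01,1.666152168383e-04,1.225133485195e-01,0.000000000000e+00,1.226799637364e-01
3.035837222257e-01,1.217229414335e-04,1.176375554179e-01,0.000000000000e+00,1.177592783593e-01
3.395866499305e-01,8.892629890637e-05,1.128069366096e-01,0.000000000000e+00,1.128958629085e-01
3.798592756079e-01,6.496627996478e-05,1.080361668394e-01,0.000000000000e+00,1.081011331194e-01
4.249079558778e-01,4.746197258415e-05,1.033375398497e-01,0.000000000000e+00,1.033850018223e-01
4.752990977496e-01,3.467397021252e-05,9.872108648074e-02,0.000000000000e+00,9.875576045095e-02
5.316662801827e-01,2.544832851368e-05,9.419480527789e-02,0.000000000000e+00,9.422025360640e-02
5.947182202147e-01,1.874836091112e-05,8.976496976202e-02,0.000000000000e+00,8.978371812293e-02
6.652476838175e-01,1.381234314628e-05,8.543647375557e-02,0.000000000000e+00,8.545028609871e-02
7.441414535185e-01,1.017586704220e-05,8.121317816575e-02,0.000000000000e+00,8.122335403279e-02
8.323914781137e-01,7.496792643918e-06,7.709822846504e-02,0.000000000000e+00,7.710572525769e-02
9.311073446592e-01,5.523057737792e-06,7.309432042044e-02,0.000000000000e+00,7.309984347818e-02
1.041530229554e+00,4.365068225829e-06,6.920390091968e-02,1.859172758102e-08,6.920828457963e-02
1.165048504124e+00,3.902284321358e-06,6.542929968619e-02,5.219528631798e-06,6.543842149915e-02
1.303215190924e+00,3.488564699771e-06,6.177279525360e-02,2.833226349343e-05,6.180461608179e-02
1.457767490233e+00,3.118707572864e-06,5.823662418575e-02,7.532047347243e-05,5.831506336679e-02
1.630648622253e+00,2.788062645270e-06,5.482294598102e-02,1.466331310744e-04,5.497236717474e-02
1.824032259651e+00,2.492472645267e-06,5.153377751696e-02,2.397128459907e-04,5.177598283559e-02
2.040349857623e+00,2.228221054482e-06,4.837091062128e-02,3.505826640516e-04,4.872372150639e-02
2.282321225119e+00,1.991985379283e-06,4.533582485528e-02,4.748175747796e-04,4.581263441544e-02
2.552988721599e+00,1.780795376337e-06,4.242960534035e-02,6.081106752654e-04,4.303949681099e-02
2.855755509295e+00,1.591995707079e-06,3.965287287387e-02,7.465769322555e-04,4.040104180183e-02
3.194428341915e+00,1.423212551557e-06,3.700573100540e-02,8.868910472472e-04,3.789404526520e-02
3.573265427806e+00,1.272323761869e-06,3.448773241618e-02,1.026323897555e-03,3.551532863750e-02
3.997029969344e+00,1.137432179927e-06,3.209786500690e-02,1.162720054671e-03,3.326172249375e-02
4.471050051729e+00,1.016841784070e-06,2.983455661052e-02,1.294443912138e-03,3.113001736445e-02
5.001285634179e+00,9.090363646089e-07,2.769569620932e-02,1.420311841317e-03,2.911691708700e-02
5.594403485815e+00,8.126604601888e-07,2.567866890500e-02,1.539521030596e-03,2.721900259606e-02
6.257861008420e+00,7.265023152715e-07,2.378040160486e-02,1.651581200711e-03,2.543270930789e-02
7.000000000000e+00,6.494786444664e-07,2.199741636864e-02,1.756252494192e-03,2.375431834148e-02
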