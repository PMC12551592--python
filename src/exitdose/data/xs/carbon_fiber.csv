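# Photon mass attenuation coefficient table for material 'carbon_fiber' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,9.506563231932e+02,1.993474528101e-01,0.000000000000e+00,9.508556706460e+02
1.118593076865e-03,6.792148303182e+02,1.992555572763e-01,0.000000000000e+00,6.794140858755e+02
1.251250471609e-03,4.852781961988e+02,1.991528911440e-01,0.000000000000e+00,4.854773490900e+02
1.399640114966e-03,3.467164101756e+02,1.990382132282e-01,0.000000000000e+00,3.469154483889e+02
1.565627742703e-03,2.477182573351e+02,1.989101380105e-01,0.000000000000e+00,2.479171674731e+02
1.751300353935e-03,1.769871088191e+02,1.987671291760e-01,0.000000000000e+00,1.771858759483e+02
1.958992451422e-03,1.264518692531e+02,1.986074775443e-01,0.000000000000e+00,1.266504767307e+02
2.191315393791e-03,9.034598815867e+01,1.984292884062e-01,0.000000000000e+00,9.054441744708e+01
2.451190228721e-03,6.454944181195e+01,1.982304598487e-01,0.000000000000e+00,6.474767227180e+01
2.741884419926e-03,4.611859943263e+01,1.980086669024e-01,0.000000000000e+00,4.631660809953e+01
3.067052929692e-03,3.295032697298e+01,1.977613365228e-01,0.000000000000e+00,3.314808830950e+01
3.430784173531e-03,2.354199956164e+01,1.974856282890e-01,0.000000000000e+00,2.373948518993e+01
3.837651424729e-03,1.682003774392e+01,1.971784100326e-01,0.000000000000e+00,1.701721615396e+01
4.292770315121e-03,1.201740187643e+01,1.968362340840e-01,0.000000000000e+00,1.221423811052e+01
4.801863155064e-03,8.586065623537e+00,1.964553131959e-01,0.000000000000e+00,8.782520936733e+00
5.371330881306e-03,6.134480951016e+00,1.960314962547e-01,0.000000000000e+00,6.330512447271e+00
6.008333537379e-03,4.382898779066e+00,1.955602447016e-01,0.000000000000e+00,4.578459023768e+00
6.720880298405e-03,3.131446957115e+00,1.950366104797e-01,0.000000000000e+00,3.326483567594e+00
7.517930172232e-03,2.237322954402e+00,1.944552161881e-01,0.000000000000e+00,2.431778170590e+00
8.409504643011e-03,1.598498735838e+00,1.938102392319e-01,0.000000000000e+00,1.792308975070e+00
9.406813673533e-03,1.142078394829e+00,1.930954007737e-01,0.000000000000e+00,1.335173795602e+00
1.052239665057e-02,8.159800384518e-01,1.923039618432e-01,0.000000000000e+00,1.008284000295e+00
1.177028004535e-02,5.829927491551e-01,1.914287283007e-01,0.000000000000e+00,7.744214774559e-01
1.316615377149e-02,4.165304658829e-01,1.904620673142e-01,0.000000000000e+00,6.069925331971e-01
1.472756845772e-02,2.975982621740e-01,1.893959378696e-01,0.000000000000e+00,4.869942000436e-01
1.647415611586e-02,2.126248447668e-01,1.882219384080e-01,0.000000000000e+00,4.008467831747e-01
1.842787697838e-02,1.519139402288e-01,1.869313746339e-01,0.000000000000e+00,3.388453148627e-01
2.061329560933e-02,1.085378581283e-01,1.855153507048e-01,0.000000000000e+00,2.940532088330e-01
2.305788975997e-02,7.754697580305e-02,1.839648868219e-01,0.000000000000e+00,2.615118626250e-01
2.579239585260e-02,5.540493943683e-02,1.822710658046e-01,0.000000000000e+00,2.376760052414e-01
2.885119543648e-02,3.958513252400e-02,1.804252105099e-01,0.000000000000e+00,2.200103430339e-01
3.227274747451e-02,2.828236494562e-02,1.784190927472e-01,0.000000000000e+00,2.067014576928e-01
3.610007189639e-02,2.020688364331e-02,1.762451726963e-01,0.000000000000e+00,1.964520563396e-01
4.038129049762e-02,1.443719955383e-02,1.738968656463e-01,0.000000000000e+00,1.883340652001e-01
4.517023198549e-02,1.031493696090e-02,1.713688301858e-01,0.000000000000e+00,1.816837671467e-01
5.052710877934e-02,7.369706577147e-03,1.686572688543e-01,0.000000000000e+00,1.760269754315e-01
5.651927407456e-02,5.265429661771e-03,1.657602288861e-01,0.000000000000e+00,1.710256585479e-01
6.322206868922e-02,3.761988246457e-03,1.626778873287e-01,0.000000000000e+00,1.664398755752e-01
7.071976834082e-02,2.687825396136e-03,1.594128018862e-01,0.000000000000e+00,1.621006272824e-01
7.910664326351e-02,1.920368934411e-03,1.559701068257e-01,0.000000000000e+00,1.578904757601e-01
8.848814348856e-02,1.372044794856e-03,1.523576327374e-01,0.000000000000e+00,1.537296775323e-01
9.898222469091e-02,9.802839888521e-04,1.485859303887e-01,0.000000000000e+00,1.495662143775e-01
1.107208312719e-01,7.126891061381e-04,1.446681827583e-01,0.000000000000e+00,1.453808718645e-01
1.238515553255e-01,5.190487944568e-04,1.406199957453e-01,0.000000000000e+00,1.411390445397e-01
1.385394923460e-01,3.780212840447e-04,1.364590667947e-01,0.000000000000e+00,1.368370880788e-01
1.549693170106e-01,2.753114788377e-04,1.322047411500e-01,0.000000000000e+00,1.324800526288e-01
1.733476051344e-01,2.005083141584e-04,1.278774765177e-01,0.000000000000e+00,1.280779848319e-01
1.939054309945e-01,1.460294507748e-04,1.234982472188e-01,0.000000000000e+00,1.236442766696e-01
2.169012726769e-01,1.063526995530e-04,1.190879268155e-01,0.000000000000e+00,1.191942795150e-01
2.426242619795e-01,7.745627092485e-05,1.146666923464e-01,0.000000000000e+00,1.147441486174e-01
2.713978197296e-01,5.641111067983e-05,1.102534926980e-01,0.000000000000e+00,1.103099038087e-01
3.035837222257e-01,4.108399965729e-05,1.058656180246e-01,0.000000000000e+00,1.059067020242e-01
3.395866499305e-01,2.992132236892e-05,1.015183970732e-01,0.000000000000e+00,1.015483183956e-01
3.798592756079e-01,2.179158650018e-05,9.722503609354e-02,0.000000000000e+00,9.724682768004e-02
4.249079558778e-01,1.587073045568e-05,9.299659859872e-02,0.000000000000e+00,9.301246932918e-02
4.752990977496e-01,1.155859327612e-05,8.884211164722e-02,0.000000000000e+00,8.885367024049e-02
5.316662801827e-01,8.441154243348e-06,8.476877337364e-02,0.000000000000e+00,8.477721452789e-02
5.947182202147e-01,6.178449261425e-06,8.078222951043e-02,0.000000000000e+00,8.078840795969e-02
6.652476838175e-01,4.522276714240e-06,7.688688415739e-02,0.000000000000e+00,7.689140643410e-02
7.441414535185e-01,3.310051732211e-06,7.308621186249e-02,0.000000000000e+00,7.308952191422e-02
8.323914781137e-01,2.422771352185e-06,6.938304333219e-02,0.000000000000e+00,6.938546610354e-02
9.311073446592e-01,1.773332110749e-06,6.577980456928e-02,0.000000000000e+00,6.578157790139e-02
1.041530229554e+00,1.395729675825e-06,6.227869760255e-02,1.450921756764e-08,6.228010784144e-02
1.165048504124e+00,1.247754616663e-06,5.888181902105e-02,4.073385659790e-06,5.888714016132e-02
1.303215190924e+00,1.115467851956e-06,5.559121934655e-02,2.211085405690e-05,5.561444566846e-02
1.457767490233e+00,9.972061109856e-07,5.240891133098e-02,5.878104292063e-05,5.246868958001e-02
1.630648622253e+00,8.914824627564e-07,4.933683837267e-02,1.144343360298e-04,4.945216419116e-02
1.824032259651e+00,7.969676204820e-07,4.637681552114e-02,1.870749138873e-04,4.656468740265e-02
2.040349857623e+00,7.124732281697e-07,4.353045529672e-02,2.735991115402e-04,4.380476688149e-02
2.282321225119e+00,6.369369191580e-07,4.079908920165e-02,3.705535952692e-04,4.117027973384e-02
2.552988721599e+00,5.694089587460e-07,3.818369376972e-02,4.745772039836e-04,3.865884038266e-02
2.855755509295e+00,5.090403029689e-07,3.568482767539e-02,5.826380089675e-04,3.626797472466e-02
3.194428341915e+00,4.550719233805e-07,3.330258410608e-02,6.921409055301e-04,3.399518008353e-02
3.573265427806e+00,4.068252636213e-07,3.103656050600e-02,8.009560520717e-04,3.183792338334e-02
3.997029969344e+00,3.636937077795e-07,2.888584605617e-02,9.074013251300e-04,2.979361107500e-02
4.471050051729e+00,3.251349532744e-07,2.684902591560e-02,1.010200276895e-03,2.785955132745e-02
5.001285634179e+00,2.906641923672e-07,2.492420031515e-02,1.108429188721e-03,2.603292016806e-02
5.594403485815e+00,2.598480165655e-07,2.310901602825e-02,1.201461536349e-03,2.431073741262e-02
6.257861008420e+00,2.322989672830e-07,2.140070748519e-02,1.288914699686e-03,2.268985448384e-02
7.000000000000e+00,2.076706642366e-07,1.979614478164e-02,1.370601490952e-03,2.116695394325e-02
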