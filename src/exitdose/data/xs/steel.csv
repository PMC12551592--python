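# Photon mass attenuation coefficient table for material 'steel' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,2.102815736771e+05,1.857922781755e-01,0.000000000000e+00,2.102817594694e+05
1.118593076865e-03,1.502397447949e+05,1.857066313296e-01,0.000000000000e+00,1.502399305015e+05
1.251250471609e-03,1.073416967608e+05,1.856109462613e-01,0.000000000000e+00,1.073418823717e+05
1.399640114966e-03,7.669235513685e+04,1.855040661837e-01,0.000000000000e+00,7.669254064091e+04
1.565627742703e-03,5.479433914247e+04,1.853846997903e-01,0.000000000000e+00,5.479452452717e+04
1.751300353935e-03,3.914887731251e+04,1.852514152322e-01,0.000000000000e+00,3.914906256392e+04
1.958992451422e-03,2.797067395675e+04,1.851026195494e-01,0.000000000000e+00,2.797085905937e+04
2.191315393791e-03,1.998418997689e+04,1.849365468685e-01,0.000000000000e+00,1.998437491343e+04
2.451190228721e-03,1.427809174887e+04,1.847512382019e-01,0.000000000000e+00,1.427827650011e+04
2.741884419926e-03,1.020125930673e+04,1.845445266728e-01,0.000000000000e+00,1.020144385126e+04
3.067052929692e-03,7.288487374471e+03,1.843140141981e-01,0.000000000000e+00,7.288671688485e+03
3.430784173531e-03,5.207401028691e+03,1.840570534989e-01,0.000000000000e+00,5.207585085744e+03
3.837651424729e-03,3.720528565171e+03,1.837707253870e-01,0.000000000000e+00,3.720712335897e+03
4.292770315121e-03,2.658203723506e+03,1.834518166268e-01,0.000000000000e+00,2.658387175323e+03
4.801863155064e-03,1.899205156442e+03,1.830967974952e-01,0.000000000000e+00,1.899388253239e+03
5.371330881306e-03,1.356923923610e+03,1.827017991447e-01,0.000000000000e+00,1.357106625409e+03
6.008333537379e-03,9.694805894036e+02,1.822625916283e-01,0.000000000000e+00,9.696628519952e+02
6.720880298405e-03,6.926641920571e+02,1.817745633457e-01,0.000000000000e+00,6.928459666204e+02
7.517930172232e-03,4.948873532922e+02,1.812327025473e-01,0.000000000000e+00,4.950685859947e+02
8.409504643011e-03,3.535818586510e+02,1.806315825612e-01,0.000000000000e+00,3.537624902336e+02
9.406813673533e-03,2.526234100254e+02,1.799653514967e-01,0.000000000000e+00,2.528033753769e+02
1.052239665057e-02,1.804916902024e+02,1.792277286184e-01,0.000000000000e+00,1.806709179311e+02
1.177028004535e-02,1.289557853283e+02,1.784120089716e-01,0.000000000000e+00,1.291341973373e+02
1.316615377149e-02,9.213495951525e+01,1.775110787396e-01,0.000000000000e+00,9.231247059399e+01
1.472756845772e-02,6.582760706132e+01,1.765174436791e-01,0.000000000000e+00,6.600412450500e+01
1.647415611586e-02,4.703180936117e+01,1.754232735180e-01,0.000000000000e+00,4.720723263469e+01
1.842787697838e-02,3.360278750106e+01,1.742204651533e-01,0.000000000000e+00,3.377700796622e+01
2.061329560933e-02,2.400816262821e+01,1.729007276396e-01,0.000000000000e+00,2.418106335585e+01
2.305788975997e-02,1.715309697935e+01,1.714556917840e-01,0.000000000000e+00,1.732455267114e+01
2.579239585260e-02,1.225536250065e+01,1.698770467540e-01,0.000000000000e+00,1.242523954740e+01
2.885119543648e-02,8.756081202305e+00,1.681567054326e-01,0.000000000000e+00,8.924237907738e+00
3.227274747451e-02,6.255951875542e+00,1.662869991275e-01,0.000000000000e+00,6.422238874669e+00
3.610007189639e-02,4.469686034752e+00,1.642609007093e-01,0.000000000000e+00,4.633946935461e+00
4.038129049762e-02,3.193453793556e+00,1.620722732122e-01,0.000000000000e+00,3.355526066768e+00
4.517023198549e-02,2.281624940161e+00,1.597161384290e-01,0.000000000000e+00,2.441341078590e+00
5.052710877934e-02,1.630151147973e+00,1.571889571177e-01,0.000000000000e+00,1.787340105091e+00
5.651927407456e-02,1.164693073985e+00,1.544889092964e-01,0.000000000000e+00,1.319181983282e+00
6.322206868922e-02,8.321375341645e-01,1.516161599736e-01,0.000000000000e+00,9.837536941380e-01
7.071976834082e-02,5.945367850397e-01,1.485730929353e-01,0.000000000000e+00,7.431098779750e-01
7.910664326351e-02,4.247783260014e-01,1.453644933303e-01,0.000000000000e+00,5.701428193317e-01
8.848814348856e-02,3.034911056488e-01,1.419976592863e-01,0.000000000000e+00,4.454887649350e-01
9.898222469091e-02,2.168351009689e-01,1.384824241423e-01,0.000000000000e+00,3.553175251112e-01
1.107208312719e-01,1.599300361478e-01,1.348310744646e-01,0.000000000000e+00,2.947611106125e-01
1.238515553255e-01,1.183364045840e-01,1.310581549864e-01,0.000000000000e+00,2.493945595704e-01
1.385394923460e-01,8.756019186366e-02,1.271801597668e-01,0.000000000000e+00,2.147403516304e-01
1.549693170106e-01,6.478806945464e-02,1.232151186163e-01,0.000000000000e+00,1.880031880709e-01
1.733476051344e-01,4.793838220679e-02,1.191820981640e-01,0.000000000000e+00,1.671204803708e-01
1.939054309945e-01,3.547085918671e-02,1.151006465246e-01,0.000000000000e+00,1.505715057113e-01
2.169012726769e-01,2.624581376184e-02,1.109902179052e-01,0.000000000000e+00,1.372360316670e-01
2.426242619795e-01,1.941996207070e-02,1.068696173519e-01,0.000000000000e+00,1.262895794226e-01
2.713978197296e-01,1.436933639207e-02,1.027565052696e-01,0.000000000000e+00,1.171258416617e-01
3.035837222257e-01,1.063224673647e-02,9.866699612147e-02,0.000000000000e+00,1.092992428579e-01
3.395866499305e-01,7.867076640189e-03,9.461537633452e-02,0.000000000000e+00,1.024824529747e-01
3.798592756079e-01,5.821055172689e-03,9.061395416333e-02,0.000000000000e+00,9.643500933602e-02
4.249079558778e-01,4.307150530400e-03,8.667304082729e-02,0.000000000000e+00,9.098019135769e-02
4.752990977496e-01,3.186973004236e-03,8.280104956535e-02,0.000000000000e+00,8.598802256959e-02
5.316662801827e-01,2.387151493552e-03,7.900468905531e-02,0.000000000000e+00,8.139184054886e-02
5.947182202147e-01,1.806197417598e-03,7.528922113258e-02,0.000000000000e+00,7.709541855018e-02
6.652476838175e-01,1.366628435669e-03,7.165875042819e-02,0.000000000000e+00,7.302537886386e-02
7.441414535185e-01,1.034036071019e-03,6.811651522872e-02,0.000000000000e+00,6.915055129974e-02
8.323914781137e-01,7.823857372367e-04,6.466515375902e-02,0.000000000000e+00,6.544753949626e-02
9.311073446592e-01,5.919788090447e-04,6.130692705919e-02,0.000000000000e+00,6.189890586823e-02
1.041530229554e+00,4.758760790133e-04,5.804388742504e-02,7.856832227464e-08,5.851984207238e-02
1.165048504124e+00,4.254237656710e-04,5.487798888234e-02,2.205763858564e-05,5.532547028660e-02
1.303215190924e+00,3.803203993212e-04,5.181114252203e-02,1.197316601817e-04,5.231119458154e-02
1.457767490233e+00,3.399988853741e-04,4.884522423346e-02,3.183030306286e-04,4.950352614946e-02
1.630648622253e+00,3.039522525270e-04,4.598204526830e-02,6.196691000437e-04,4.690566662087e-02
1.824032259651e+00,2.717272785014e-04,4.322329725680e-02,1.013022380792e-03,4.450804691609e-02
2.040349857623e+00,2.429187915798e-04,4.057048307157e-02,1.481556332679e-03,4.229495819583e-02
2.282321225119e+00,2.171645762914e-04,3.802484367573e-02,2.006570937228e-03,4.024857918925e-02
2.552988721599e+00,1.941408191977e-04,3.558728920097e-02,2.569865296524e-03,3.835129531669e-02
2.855755509295e+00,1.735580375143e-04,3.325834033318e-02,3.155021326589e-03,3.658691969728e-02
3.194428341915e+00,1.551574393798e-04,3.103808392321e-02,3.747986372914e-03,3.494122773551e-02
3.573265427806e+00,1.387076700087e-04,2.892614478819e-02,4.337227209782e-03,3.340207966798e-02
3.997029969344e+00,1.240019028166e-04,2.692167404273e-02,4.913635033241e-03,3.195931097878e-02
4.471050051729e+00,1.108552389437e-04,2.502335305183e-02,5.470297798418e-03,3.060450608920e-02
5.001285634179e+00,9.910238248073e-05,2.322941122636e-02,6.002213510968e-03,2.933072711981e-02
5.594403485815e+00,8.859556216681e-05,2.153765535380e-02,6.505989502768e-03,2.813224041874e-02
6.257861008420e+00,7.920267342897e-05,1.994550791691e-02,6.979553862044e-03,2.700426445239e-02
7.000000000000e+00,7.080561740197e-05,1.845005183776e-02,7.421892955239e-03,2.594275041040e-02
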