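# Photon mass attenuation coefficient table for material 'aluminum' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,1.920616459843e+04,1.922683599198e-01,0.000000000000e+00,1.920635686679e+04
1.118593076865e-03,1.372221644197e+04,1.921797277185e-01,0.000000000000e+00,1.372240862170e+04
1.251250471609e-03,9.804103422902e+03,1.920807073968e-01,0.000000000000e+00,9.804295503610e+03
1.399640114966e-03,7.004731657852e+03,1.919701018463e-01,0.000000000000e+00,7.004923627954e+03
1.565627742703e-03,5.004666258814e+03,1.918465747497e-01,0.000000000000e+00,5.004858105388e+03
1.751300353935e-03,3.575680780581e+03,1.917086443489e-01,0.000000000000e+00,3.575872489225e+03
1.958992451422e-03,2.554714417190e+03,1.915546621588e-01,0.000000000000e+00,2.554905971852e+03
2.191315393791e-03,1.825265216303e+03,1.913828007536e-01,0.000000000000e+00,1.825456599104e+03
2.451190228721e-03,1.304096100695e+03,1.911910328623e-01,0.000000000000e+00,1.304287291727e+03
2.741884419926e-03,9.317367277132e+02,1.909771160782e-01,0.000000000000e+00,9.319277048293e+02
3.067052929692e-03,6.656973587356e+02,1.907385687290e-01,0.000000000000e+00,6.658880973043e+02
3.430784173531e-03,4.756203767079e+02,1.904726512609e-01,0.000000000000e+00,4.758108493591e+02
3.837651424729e-03,3.398161939074e+02,1.901763427329e-01,0.000000000000e+00,3.400063702501e+02
4.292770315121e-03,2.427882641215e+02,1.898463179068e-01,0.000000000000e+00,2.429781104394e+02
4.801863155064e-03,1.734647796426e+02,1.894789240256e-01,0.000000000000e+00,1.736542585666e+02
5.371330881306e-03,1.239352729232e+02,1.890701573870e-01,0.000000000000e+00,1.241243430806e+02
6.008333537379e-03,8.854795714842e+01,1.886156406027e-01,0.000000000000e+00,8.873657278902e+01
6.720880298405e-03,6.326480371747e+01,1.881106013276e-01,0.000000000000e+00,6.345291431879e+01
7.517930172232e-03,4.520076485447e+01,1.875498531198e-01,0.000000000000e+00,4.538831470759e+01
8.409504643011e-03,3.229456227437e+01,1.869277801522e-01,0.000000000000e+00,3.248149005452e+01
9.406813673533e-03,2.307347576641e+01,1.862383265573e-01,0.000000000000e+00,2.325971409297e+01
1.052239665057e-02,1.648529184016e+01,1.854749926747e-01,0.000000000000e+00,1.667076683284e+01
1.177028004535e-02,1.177823617935e+01,1.846308398380e-01,0.000000000000e+00,1.196286701919e+01
1.316615377149e-02,8.415189057107e+00,1.836985062674e-01,0.000000000000e+00,8.598887563375e+00
1.472756845772e-02,6.012394877173e+00,1.826702364958e-01,0.000000000000e+00,6.195065113669e+00
1.647415611586e-02,4.295672018031e+00,1.815379273147e-01,0.000000000000e+00,4.477209945346e+00
1.842787697838e-02,3.069126107560e+00,1.802931931748e-01,0.000000000000e+00,3.249419300735e+00
2.061329560933e-02,2.192796615889e+00,1.789274541367e-01,0.000000000000e+00,2.371724070026e+00
2.305788975997e-02,1.566686030532e+00,1.774320492862e-01,0.000000000000e+00,1.744118079818e+00
2.579239585260e-02,1.119349191110e+00,1.757983781035e-01,0.000000000000e+00,1.295147569213e+00
2.885119543648e-02,7.997407184467e-01,1.740180715826e-01,0.000000000000e+00,9.737587900293e-01
3.227274747451e-02,5.713902523193e-01,1.720831937268e-01,0.000000000000e+00,7.434734460462e-01
3.610007189639e-02,4.082408372049e-01,1.699864724651e-01,0.000000000000e+00,5.782273096701e-01
4.038129049762e-02,2.916755763426e-01,1.677215569182e-01,0.000000000000e+00,4.593971332608e-01
4.517023198549e-02,2.083932671147e-01,1.652832953556e-01,0.000000000000e+00,3.736765624703e-01
5.052710877934e-02,1.488906075829e-01,1.626680251694e-01,0.000000000000e+00,3.115586327523e-01
5.651927407456e-02,1.063777795384e-01,1.598738629393e-01,0.000000000000e+00,2.662516424777e-01
6.322206868922e-02,7.600366580017e-02,1.569009794256e-01,0.000000000000e+00,2.329046452258e-01
7.071976834082e-02,5.430229170162e-02,1.537518415050e-01,0.000000000000e+00,2.080541332066e-01
7.910664326351e-02,3.879732448433e-02,1.504314011198e-01,0.000000000000e+00,1.892287256041e-01
8.848814348856e-02,2.771950022686e-02,1.469472107857e-01,0.000000000000e+00,1.746667110126e-01
9.898222469091e-02,1.980473403875e-02,1.433094465982e-01,0.000000000000e+00,1.631141806369e-01
1.107208312719e-01,1.450821522219e-02,1.395308233911e-01,0.000000000000e+00,1.540390386133e-01
1.238515553255e-01,1.065491466909e-02,1.356263928771e-01,0.000000000000e+00,1.462813075461e-01
1.385394923460e-01,7.825029120879e-03,1.316132240415e-01,0.000000000000e+00,1.394382531624e-01
1.549693170106e-01,5.746745294941e-03,1.275099751525e-01,0.000000000000e+00,1.332567204474e-01
1.733476051344e-01,4.220441991303e-03,1.233363774363e-01,0.000000000000e+00,1.275568194276e-01
1.939054309945e-01,3.099516280569e-03,1.191126603877e-01,0.000000000000e+00,1.222121766683e-01
2.169012726769e-01,2.276302148758e-03,1.148589563212e-01,0.000000000000e+00,1.171352584699e-01
2.426242619795e-01,1.671729071057e-03,1.105947257619e-01,0.000000000000e+00,1.122664548330e-01
2.713978197296e-01,1.227727210354e-03,1.063382446961e-01,0.000000000000e+00,1.075659719065e-01
3.035837222257e-01,9.016497524265e-04,1.021061892818e-01,0.000000000000e+00,1.030078390342e-01
3.395866499305e-01,6.621766376071e-04,9.791334392190e-02,0.000000000000e+00,9.857552055951e-02
3.798592756079e-01,4.863062383289e-04,9.377244589451e-02,0.000000000000e+00,9.425875213284e-02
4.249079558778e-01,3.571460302378e-04,8.969416583278e-02,0.000000000000e+00,9.005131186302e-02
4.752990977496e-01,2.622900486593e-04,8.568721023232e-02,0.000000000000e+00,8.594950028098e-02
5.316662801827e-01,1.941249674671e-04,8.175852161244e-02,0.000000000000e+00,8.195264657991e-02
5.947182202147e-01,1.445959305277e-04,7.791354521809e-02,0.000000000000e+00,7.805814114862e-02
6.652476838175e-01,1.077037302207e-04,7.415652875366e-02,0.000000000000e+00,7.426423248388e-02
7.441414535185e-01,8.022420452030e-05,7.049082338129e-02,0.000000000000e+00,7.057104758581e-02
8.323914781137e-01,5.975580397934e-05,6.691915928531e-02,0.000000000000e+00,6.697891508929e-02
9.311073446592e-01,4.450971038690e-05,6.344387631792e-02,0.000000000000e+00,6.348838602831e-02
1.041530229554e+00,3.542457920183e-05,6.006709831094e-02,3.539090320291e-08,6.010255828105e-02
1.165048504124e+00,3.166887041811e-05,5.679084740076e-02,9.935807835380e-06,5.683245207901e-02
1.303215190924e+00,2.831134133860e-05,5.361710129240e-02,5.393282525496e-05,5.369934545899e-02
1.457767490233e+00,2.530977700842e-05,5.054780126228e-02,1.433787997507e-04,5.071648983904e-02
1.630648622253e+00,2.262643809611e-05,4.758482169609e-02,2.791283879121e-04,4.788657652210e-02
1.824032259651e+00,2.022758638873e-05,4.472991318853e-02,4.563133841102e-04,4.520645415903e-02
2.040349857623e+00,1.808306059378e-05,4.198463099718e-02,6.673633245752e-04,4.267007738235e-02
2.282321225119e+00,1.616589711468e-05,3.935025934088e-02,9.038548330074e-04,4.027028007100e-02
2.552988721599e+00,1.445199103144e-05,3.682774007539e-02,1.157589360708e-03,3.799978142713e-02
2.855755509295e+00,1.291979302424e-05,3.441761203592e-02,1.421171423034e-03,3.585170325198e-02
3.194428341915e+00,1.155003842903e-05,3.211996510066e-02,1.688271037098e-03,3.381978617618e-02
3.573265427806e+00,1.032550501869e-05,2.993441100912e-02,1.953693090376e-03,3.189842960452e-02
3.997029969344e+00,9.230796464098e-06,2.786007128671e-02,2.213334545034e-03,3.008263662821e-02
4.471050051729e+00,8.252148752764e-06,2.589558133533e-02,2.464081887840e-03,2.836791537192e-02
5.001285634179e+00,7.377257130800e-06,2.403910884916e-02,2.703681983018e-03,2.675016808931e-02
5.594403485815e+00,6.595121392561e-06,2.228838416784e-02,2.930606611743e-03,2.522558590097e-02
6.257861008420e+00,5.895907572615e-06,2.064073993070e-02,3.143922486567e-03,2.379055832483e-02
7.000000000000e+00,5.270824301131e-06,1.909315738047e-02,3.343173018803e-03,2.244160122358e-02
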