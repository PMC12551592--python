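# Photon mass attenuation coefficient table for material 'lead' (generated by tools/build_xs_tables.py)
# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,mu_rho_pair,mu_rho_total  [MeV, cm^2/g]
1.000000000000e-03,1.123658223564e+05,1.579292993626e-01,0.000000000000e+00,1.123659802857e+05
1.118593076865e-03,8.028193901765e+04,1.578564968409e-01,0.000000000000e+00,8.028209687414e+04
1.251250471609e-03,5.735898689900e+04,1.577751615134e-01,0.000000000000e+00,5.735914467416e+04
1.399640114966e-03,4.098123959557e+04,1.576843100747e-01,0.000000000000e+00,4.098139727988e+04
1.565627742703e-03,2.927984069431e+04,1.575828448736e-01,0.000000000000e+00,2.927999827716e+04
1.751300353935e-03,2.091954951936e+04,1.574695487932e-01,0.000000000000e+00,2.091970698891e+04
1.958992451422e-03,1.494637749781e+04,1.573430677674e-01,0.000000000000e+00,1.494653484088e+04
2.191315393791e-03,1.067872900897e+04,1.572019007479e-01,0.000000000000e+00,1.067888621087e+04
2.451190228721e-03,7.629624854838e+03,1.570443825337e-01,0.000000000000e+00,7.629781899220e+03
2.741884419926e-03,5.451133311525e+03,1.568686712110e-01,0.000000000000e+00,5.451290180196e+03
3.067052929692e-03,3.894667817275e+03,1.566727283333e-01,0.000000000000e+00,3.894824490003e+03
3.430784173531e-03,2.782620886348e+03,1.564543036302e-01,0.000000000000e+00,2.782777340652e+03
3.837651424729e-03,1.988097409180e+03,1.562109156997e-01,0.000000000000e+00,1.988253620095e+03
4.292770315121e-03,1.420434715983e+03,1.559398331900e-01,0.000000000000e+00,1.420590655816e+03
4.801863155064e-03,1.014857105619e+03,1.556380557250e-01,0.000000000000e+00,1.015012743675e+03
5.371330881306e-03,7.250843232967e+02,1.553022946624e-01,0.000000000000e+00,7.252396255914e+02
6.008333537379e-03,5.180505442389e+02,1.549289544137e-01,0.000000000000e+00,5.182054731933e+02
6.720880298405e-03,3.701312492401e+02,1.545141149732e-01,0.000000000000e+00,3.702857633551e+02
7.517930172232e-03,2.644474427979e+02,1.540535161954e-01,0.000000000000e+00,2.646014963141e+02
8.409504643011e-03,1.889395995229e+02,1.535425452381e-01,0.000000000000e+00,1.890931420681e+02
9.406813673533e-03,1.349915578316e+02,1.529762278095e-01,0.000000000000e+00,1.351445340594e+02
1.052239665057e-02,9.644733413126e+01,1.523492250863e-01,0.000000000000e+00,9.659968335634e+01
1.177028004535e-02,6.890866666364e+01,1.516558376455e-01,0.000000000000e+00,6.906032250129e+01
1.316615377149e-02,4.923313209362e+02,1.508900185182e-01,0.000000000000e+00,4.924822109547e+02
1.472756845772e-02,3.517556518078e+02,1.500453973614e-01,0.000000000000e+00,3.519056972051e+02
1.647415611586e-02,2.513186411611e+02,1.491153181965e-01,0.000000000000e+00,2.514677564793e+02
1.842787697838e-02,1.795594728057e+02,1.480928931304e-01,0.000000000000e+00,1.797075656989e+02
2.061329560933e-02,1.282897445463e+02,1.469710745977e-01,0.000000000000e+00,1.284367156209e+02
2.305788975997e-02,9.165909377313e+01,1.457427485205e-01,0.000000000000e+00,9.180483652165e+01
2.579239585260e-02,6.548761556134e+01,1.444008504288e-01,0.000000000000e+00,6.563201641177e+01
2.885119543648e-02,4.678889584622e+01,1.429385060181e-01,0.000000000000e+00,4.693183435224e+01
3.227274747451e-02,3.342923323355e+01,1.413491966577e-01,0.000000000000e+00,3.357058243020e+01
3.610007189639e-02,2.388416341894e+01,1.396269490661e-01,0.000000000000e+00,2.402379036800e+01
4.038129049762e-02,1.706450334164e+01,1.377665466286e-01,0.000000000000e+00,1.720226988827e+01
4.517023198549e-02,1.219206505957e+01,1.357637577121e-01,0.000000000000e+00,1.232782881728e+01
5.052710877934e-02,8.710857119054e+00,1.336155738491e-01,0.000000000000e+00,8.844472692903e+00
5.651927407456e-02,6.223640652987e+00,1.313204479974e-01,0.000000000000e+00,6.354961100985e+00
6.322206868922e-02,4.446600655725e+00,1.288785204198e-01,0.000000000000e+00,4.575479176145e+00
7.071976834082e-02,3.176959997201e+00,1.262918174094e-01,0.000000000000e+00,3.303251814611e+00
7.910664326351e-02,2.269840627766e+00,1.235644064936e-01,0.000000000000e+00,2.393405034260e+00
8.848814348856e-02,7.722531512601e+00,1.207024913114e-01,0.000000000000e+00,7.843234003913e+00
9.898222469091e-02,5.517512273352e+00,1.177144305113e-01,0.000000000000e+00,5.635226703864e+00
1.107208312719e-01,4.115677237522e+00,1.146106680623e-01,0.000000000000e+00,4.230287905585e+00
1.238515553255e-01,3.083323900807e+00,1.114035674465e-01,0.000000000000e+00,3.194727468254e+00
1.385394923460e-01,2.309920270379e+00,1.081071491347e-01,0.000000000000e+00,2.418027419514e+00
1.549693170106e-01,1.730512857929e+00,1.047367390348e-01,0.000000000000e+00,1.835249596964e+00
1.733476051344e-01,1.296440742938e+00,1.013085443833e-01,0.000000000000e+00,1.397749287321e+00
1.939054309945e-01,9.712488365798e-01,9.783918169429e-02,0.000000000000e+00,1.069088018274e+00
2.169012726769e-01,7.276262395301e-01,9.434518765798e-02,0.000000000000e+00,8.219714271880e-01
2.426242619795e-01,5.451125648882e-01,9.084254715684e-02,0.000000000000e+00,6.359551120450e-01
2.713978197296e-01,4.083795941593e-01,8.734627209240e-02,0.000000000000e+00,4.957258662517e-01
3.035837222257e-01,3.059439529887e-01,8.387006026676e-02,0.000000000000e+00,3.898140132555e-01
3.395866499305e-01,2.292026920764e-01,8.042605559380e-02,0.000000000000e+00,3.096287476702e-01
3.798592756079e-01,1.717107775521e-01,7.702472047828e-02,0.000000000000e+00,2.487354980304e-01
4.249079558778e-01,1.286398116028e-01,7.367481978208e-02,0.000000000000e+00,2.023146313848e-01
4.752990977496e-01,9.637252457360e-02,7.038350502378e-02,0.000000000000e+00,1.667560295974e-01
5.316662801827e-01,7.363345076282e-02,6.715647879122e-02,0.000000000000e+00,1.407899295540e-01
5.947182202147e-01,5.718027696867e-02,6.399821381055e-02,0.000000000000e+00,1.211784907792e-01
6.652476838175e-01,4.440351552646e-02,6.091219914767e-02,0.000000000000e+00,1.053157146741e-01
7.441414535185e-01,3.448168311932e-02,5.790118744835e-02,0.000000000000e+00,9.238287056767e-02
8.323914781137e-01,2.677685441444e-02,5.496742128697e-02,0.000000000000e+00,8.174427570140e-02
9.311073446592e-01,2.079364658189e-02,5.211282261896e-02,0.000000000000e+00,7.290646920086e-02
1.041530229554e+00,1.699442850080e-02,4.933913596054e-02,2.650276180586e-07,6.633382948896e-02
1.165048504124e+00,1.519268163936e-02,4.664802229526e-02,7.440509412832e-05,6.191510902875e-02
1.303215190924e+00,1.358195572061e-02,4.404110611073e-02,4.038802889698e-04,5.802694212031e-02
1.457767490233e+00,1.214199873173e-02,4.151998197209e-02,1.073703645261e-03,5.473568434908e-02
1.630648622253e+00,1.085470577537e-02,3.908618950042e-02,2.090275327441e-03,5.203117060323e-02
1.824032259651e+00,9.703891432795e-03,3.674116663482e-02,3.417139387080e-03,4.986219745469e-02
2.040349857623e+00,8.675086261033e-03,3.448619086442e-02,4.997603798857e-03,4.815888092431e-02
2.282321225119e+00,7.755354865371e-03,3.232231704704e-02,6.768589433542e-03,4.684626134596e-02
2.552988721599e+00,6.933133259781e-03,3.025031882334e-02,8.668700801431e-03,4.585215288456e-02
2.855755509295e+00,6.198083470367e-03,2.827063879275e-02,1.064255622243e-02,4.511127848555e-02
3.194428341915e+00,5.540963553734e-03,2.638335078125e-02,1.264275311184e-02,4.456706744682e-02
3.573265427806e+00,4.953511395999e-03,2.458813587153e-02,1.463038745271e-02,4.417203472024e-02
3.997029969344e+00,4.428340831398e-03,2.288427248424e-02,1.657473331704e-02,4.388734663268e-02
4.471050051729e+00,3.958848774400e-03,2.127063973803e-02,1.845247491118e-02,4.368196342361e-02
5.001285634179e+00,3.539132197650e-03,1.974573257625e-02,2.024673944711e-02,4.353160422101e-02
5.594403485815e+00,3.163913911903e-03,1.830768669905e-02,2.194608273555e-02,4.341768334650e-02
6.257861008420e+00,2.828476214756e-03,1.695431113544e-02,2.354351577858e-02,4.332630312877e-02
7.000000000000e+00,2.528601573938e-03,1.568312627713e-02,2.503561937516e-02,4.324734722623e-02
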