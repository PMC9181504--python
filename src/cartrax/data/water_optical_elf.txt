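# Optical (k=0) energy-loss function of liquid water, outer shells
# provenance: synthetic table evaluated from the packaged Mermin-oscillator fixture at k=0 (Drude limit); serves as the fit target for fit_optical_elf and mirrors the fixture exactly.
# E_eV	ELF
7.050000e+00	5.25910701e-02
7.383019e+00	5.62522862e-02
7.716038e+00	6.01217980e-02
8.049057e+00	6.42217709e-02
8.382075e+00	6.85770334e-02
8.715094e+00	7.32154919e-02
9.048113e+00	7.81686200e-02
9.381132e+00	8.34720368e-02
9.714151e+00	8.91661935e-02
1.004717e+01	9.52971889e-02
1.038019e+01	1.01917743e-01
1.071321e+01	1.09088359e-01
1.104623e+01	1.16878715e-01
1.137925e+01	1.25369326e-01
1.171226e+01	1.34653535e-01
1.204528e+01	1.44839884e-01
1.237830e+01	1.56054915e-01
1.271132e+01	1.68446468e-01
1.304434e+01	1.82187465e-01
1.337736e+01	1.97480146e-01
1.371038e+01	2.14560567e-01
1.404340e+01	2.33702931e-01
1.437642e+01	2.55222894e-01
1.470943e+01	2.79478238e-01
1.504245e+01	3.06864218e-01
1.537547e+01	3.37799188e-01
1.570849e+01	3.72694233e-01
1.604151e+01	4.11899119e-01
1.637453e+01	4.55618471e-01
1.670755e+01	5.03801327e-01
1.704057e+01	5.56030105e-01
1.737358e+01	6.11471668e-01
1.770660e+01	6.68982449e-01
1.803962e+01	7.27428507e-01
1.837264e+01	7.86143286e-01
1.870566e+01	8.45259282e-01
1.903868e+01	9.05605532e-01
1.937170e+01	9.68082952e-01
1.970472e+01	1.03276009e+00
2.003774e+01	1.09811464e+00
2.037075e+01	1.16082543e+00
2.070377e+01	1.21637043e+00
2.103679e+01	1.26037655e+00
2.136981e+01	1.29017355e+00
2.170283e+01	1.30565846e+00
2.203585e+01	1.30887726e+00
2.236887e+01	1.30259577e+00
2.270189e+01	1.28878035e+00
2.303491e+01	1.26781160e+00
2.336792e+01	1.23868344e+00
2.370094e+01	1.19991200e+00
2.403396e+01	1.15062048e+00
2.436698e+01	1.09127869e+00
2.470000e+01	1.02381588e+00
2.503302e+01	9.51171216e-01
2.536604e+01	8.76592771e-01
2.569906e+01	8.03015583e-01
2.603208e+01	7.32698131e-01
2.636509e+01	6.67124750e-01
2.669811e+01	6.07086854e-01
2.703113e+01	5.52843380e-01
2.736415e+01	5.04290020e-01
2.769717e+01	4.61101937e-01
2.803019e+01	4.22839511e-01
2.836321e+01	3.89019763e-01
2.869623e+01	3.59160814e-01
2.902925e+01	3.32807194e-01
2.936226e+01	3.09542447e-01
2.969528e+01	2.88993807e-01
3.002830e+01	2.70832199e-01
3.036132e+01	2.54769700e-01
3.069434e+01	2.40555787e-01
3.102736e+01	2.27973154e-01
3.136038e+01	2.16833550e-01
3.169340e+01	2.06973874e-01
3.202642e+01	1.98252637e-01
3.235943e+01	1.90546809e-01
3.269245e+01	1.83749058e-01
3.302547e+01	1.77765346e-01
3.335849e+01	1.72512840e-01
3.369151e+01	1.67918102e-01
3.402453e+01	1.63915522e-01
3.435755e+01	1.60445959e-01
3.469057e+01	1.57455559e-01
3.502358e+01	1.54894738e-01
3.535660e+01	1.52717297e-01
3.568962e+01	1.50879669e-01
3.602264e+01	1.49340292e-01
3.635566e+01	1.48059083e-01
3.668868e+01	1.46997051e-01
3.702170e+01	1.46116003e-01
3.735472e+01	1.45378393e-01
3.768774e+01	1.44747277e-01
3.802075e+01	1.44186403e-01
3.835377e+01	1.43660408e-01
3.868679e+01	1.43135138e-01
3.901981e+01	1.42578053e-01
3.935283e+01	1.41958709e-01
3.968585e+01	1.41249279e-01
4.001887e+01	1.40425086e-01
4.035189e+01	1.39465105e-01
4.068491e+01	1.38352387e-01
4.101792e+01	1.37074388e-01
4.135094e+01	1.35623155e-01
4.168396e+01	1.33995361e-01
4.201698e+01	1.32192178e-01
4.235000e+01	1.30218988e-01
4.268302e+01	1.28084964e-01
4.301604e+01	1.25802530e-01
4.334906e+01	1.23386749e-01
4.368208e+01	1.20854664e-01
4.401509e+01	1.18224638e-01
4.434811e+01	1.15515720e-01
4.468113e+01	1.12747068e-01
4.501415e+01	1.09937445e-01
4.534717e+01	1.07104796e-01
4.568019e+01	1.04265924e-01
4.601321e+01	1.01436253e-01
4.634623e+01	9.86296687e-02
4.667925e+01	9.58584385e-02
4.701226e+01	9.31331942e-02
4.734528e+01	9.04629622e-02
4.767830e+01	8.78552341e-02
4.801132e+01	8.53160657e-02
4.834434e+01	8.28501931e-02
4.867736e+01	8.04611607e-02
4.901038e+01	7.81514516e-02
4.934340e+01	7.59226183e-02
4.967642e+01	7.37754071e-02
5.000943e+01	7.17098762e-02
5.034245e+01	6.97255040e-02
5.067547e+01	6.78212878e-02
5.100849e+01	6.59958318e-02
5.134151e+01	6.42474252e-02
5.167453e+01	6.25741104e-02
5.200755e+01	6.09737423e-02
5.234057e+01	5.94440384e-02
5.267358e+01	5.79826219e-02
5.300660e+01	5.65870582e-02
5.333962e+01	5.52548843e-02
5.367264e+01	5.39836339e-02
5.400566e+01	5.27708574e-02
5.433868e+01	5.16141380e-02
5.467170e+01	5.05111045e-02
5.500472e+01	4.94594408e-02
5.533774e+01	4.84568938e-02
5.567075e+01	4.75012782e-02
5.600377e+01	4.65904805e-02
5.633679e+01	4.57224610e-02
5.666981e+01	4.48952550e-02
5.700283e+01	4.41069728e-02
5.733585e+01	4.33557994e-02
5.766887e+01	4.26399927e-02
5.800189e+01	4.19578824e-02
5.833491e+01	4.13078678e-02
5.866792e+01	4.06884155e-02
5.900094e+01	4.00980568e-02
5.933396e+01	3.95353856e-02
5.966698e+01	3.89990551e-02
6.000000e+01	3.84877756e-02
6.293041e+01	3.48917401e-02
6.600394e+01	3.23681171e-02
6.922758e+01	3.04872734e-02
7.260867e+01	2.88618125e-02
7.615488e+01	2.71640964e-02
7.987430e+01	2.51754441e-02
8.377537e+01	2.28324431e-02
8.786697e+01	2.02240188e-02
9.215841e+01	1.75283086e-02
9.665944e+01	1.49288747e-02
1.013803e+02	1.25580390e-02
1.063317e+02	1.04821740e-02
1.115250e+02	8.71444401e-03
1.169719e+02	7.23546158e-03
1.226848e+02	6.01068734e-03
1.286767e+02	5.00160363e-03
1.349613e+02	4.17162596e-03
1.415529e+02	3.48860872e-03
1.484663e+02	2.92547396e-03
1.557174e+02	2.45994309e-03
1.633227e+02	2.07391862e-03
1.712994e+02	1.75279029e-03
1.796657e+02	1.48478784e-03
1.884406e+02	1.26042431e-03
1.976441e+02	1.07203706e-03
2.072970e+02	9.13417778e-04
2.174214e+02	7.79518107e-04
2.280403e+02	6.66216717e-04
2.391779e+02	5.70135520e-04
2.508593e+02	4.88494542e-04
2.631113e+02	4.18997126e-04
2.759617e+02	3.59738829e-04
2.894398e+02	3.09134868e-04
3.035760e+02	2.65862084e-04
3.184027e+02	2.28812325e-04
3.339536e+02	1.97054831e-04
3.502639e+02	1.69805749e-04
3.673708e+02	1.46403317e-04
3.853133e+02	1.26287572e-04
4.041320e+02	1.08983704e-04
4.238699e+02	9.40883339e-05
4.445718e+02	8.12581608e-05
4.662847e+02	7.02005460e-05
4.890581e+02	6.06656681e-05
5.129438e+02	5.24399709e-05
5.379961e+02	4.53406743e-05
5.642719e+02	3.92111632e-05
5.918310e+02	3.39171045e-05
6.207361e+02	2.93431695e-05
6.510529e+02	2.53902607e-05
6.828504e+02	2.19731612e-05
7.162010e+02	1.90185391e-05
7.511803e+02	1.64632486e-05
7.878681e+02	1.42528837e-05
8.263477e+02	1.23405434e-05
8.667066e+02	1.06857766e-05
9.090367e+02	9.25367969e-06
9.534341e+02	8.01412387e-06
1.000000e+03	6.94109215e-06
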