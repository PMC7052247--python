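# Synthetic parametric vocal-tract geometry (not anatomical data).
# Omega(x) = 1.5 + 0.4 sin(pi x / L) cm; phi1 = cos(pi x/L); phi2 = cos(2 pi x/L);
# L = 17.5 cm, 101 points. Stand-in for MRI-derived orthogonal decompositions,
# which are not redistributable. Swappable via ccvmotor.tract_model.load_geometry.
x,omega,phi1,phi2
0,1.5,1,1
0.175,1.512564304,0.9995065604,0.9980267284
0.35,1.525116208,0.9980267284,0.9921147013
0.525,1.537643325,0.9955619646,0.9822872507
0.7,1.550133293,0.9921147013,0.9685831611
0.875,1.562573786,0.9876883406,0.9510565163
1.05,1.574952526,0.9822872507,0.9297764859
1.225,1.587257297,0.9759167619,0.9048270525
1.4,1.599475955,0.9685831611,0.87630668
1.575,1.611596442,0.9602936857,0.8443279255
1.75,1.623606798,0.9510565163,0.8090169944
1.925,1.635495168,0.940880769,0.7705132428
2.1,1.647249821,0.9297764859,0.7289686274
2.275,1.658859156,0.9177546257,0.6845471059
2.45,1.670311717,0.9048270525,0.6374239897
2.625,1.6815962,0.8910065242,0.5877852523
2.8,1.69270147,0.87630668,0.535826795
2.975,1.703616566,0.860742027,0.4817536741
3.15,1.714330718,0.8443279255,0.4257792916
3.325,1.724833351,0.8270805743,0.3681245527
3.5,1.735114101,0.8090169944,0.3090169944
3.675,1.745162821,0.7901550124,0.2486898872
3.85,1.754969596,0.7705132428,0.1873813146
4.025,1.764524746,0.7501110696,0.1253332336
4.2,1.773818842,0.7289686274,0.06279051953
4.375,1.782842712,0.7071067812,6.123233996e-17
4.55,1.791587451,0.6845471059,-0.06279051953
4.725,1.800044428,0.6613118653,-0.1253332336
4.9,1.808205297,0.6374239897,-0.1873813146
5.075,1.816062005,0.6129070537,-0.2486898872
5.25,1.823606798,0.5877852523,-0.3090169944
5.425,1.83083223,0.5620833779,-0.3681245527
5.6,1.83773117,0.535826795,-0.4257792916
5.775,1.844296811,0.5090414158,-0.4817536741
5.95,1.850522672,0.4817536741,-0.535826795
6.125,1.85640261,0.4539904997,-0.5877852523
6.3,1.861930821,0.4257792916,-0.6374239897
6.475,1.86710185,0.3971478906,-0.6845471059
6.65,1.871910594,0.3681245527,-0.7289686274
6.825,1.876352308,0.3387379202,-0.7705132428
7,1.880422607,0.3090169944,-0.8090169944
7.175,1.884117474,0.278991106,-0.8443279255
7.35,1.887433264,0.2486898872,-0.87630668
7.525,1.890366705,0.2181432414,-0.9048270525
7.7,1.8929149,0.1873813146,-0.9297764859
7.875,1.895075336,0.156434465,-0.9510565163
8.05,1.896845881,0.1253332336,-0.9685831611
8.225,1.898224786,0.09410831332,-0.9822872507
8.4,1.899210691,0.06279051953,-0.9921147013
8.575,1.899802624,0.03141075908,-0.9980267284
8.75,1.9,6.123233996e-17,-1
8.925,1.899802624,-0.03141075908,-0.9980267284
9.1,1.899210691,-0.06279051953,-0.9921147013
9.275,1.898224786,-0.09410831332,-0.9822872507
9.45,1.896845881,-0.1253332336,-0.9685831611
9.625,1.895075336,-0.156434465,-0.9510565163
9.8,1.8929149,-0.1873813146,-0.9297764859
9.975,1.890366705,-0.2181432414,-0.9048270525
10.15,1.887433264,-0.2486898872,-0.87630668
10.325,1.884117474,-0.278991106,-0.8443279255
10.5,1.880422607,-0.3090169944,-0.8090169944
10.675,1.876352308,-0.3387379202,-0.7705132428
10.85,1.871910594,-0.3681245527,-0.7289686274
11.025,1.86710185,-0.3971478906,-0.6845471059
11.2,1.861930821,-0.4257792916,-0.6374239897
11.375,1.85640261,-0.4539904997,-0.5877852523
11.55,1.850522672,-0.4817536741,-0.535826795
11.725,1.844296811,-0.5090414158,-0.4817536741
11.9,1.83773117,-0.535826795,-0.4257792916
12.075,1.83083223,-0.5620833779,-0.3681245527
12.25,1.823606798,-0.5877852523,-0.3090169944
12.425,1.816062005,-0.6129070537,-0.2486898872
12.6,1.808205297,-0.6374239897,-0.1873813146
12.775,1.800044428,-0.6613118653,-0.1253332336
12.95,1.791587451,-0.6845471059,-0.06279051953
13.125,1.782842712,-0.7071067812,-1.836970199e-16
13.3,1.773818842,-0.7289686274,0.06279051953
13.475,1.764524746,-0.7501110696,0.1253332336
13.65,1.754969596,-0.7705132428,0.1873813146
13.825,1.745162821,-0.7901550124,0.2486898872
14,1.735114101,-0.8090169944,0.3090169944
14.175,1.724833351,-0.8270805743,0.3681245527
14.35,1.714330718,-0.8443279255,0.4257792916
14.525,1.703616566,-0.860742027,0.4817536741
14.7,1.69270147,-0.87630668,0.535826795
14.875,1.6815962,-0.8910065242,0.5877852523
15.05,1.670311717,-0.9048270525,0.6374239897
15.225,1.658859156,-0.9177546257,0.6845471059
15.4,1.647249821,-0.9297764859,0.7289686274
15.575,1.635495168,-0.940880769,0.7705132428
15.75,1.623606798,-0.9510565163,0.8090169944
15.925,1.611596442,-0.9602936857,0.8443279255
16.1,1.599475955,-0.9685831611,0.87630668
16.275,1.587257297,-0.9759167619,0.9048270525
16.45,1.574952526,-0.9822872507,0.9297764859
16.625,1.562573786,-0.9876883406,0.9510565163
16.8,1.550133293,-0.9921147013,0.9685831611
16.975,1.537643325,-0.9955619646,0.9822872507
17.15,1.525116208,-0.9980267284,0.9921147013
17.325,1.512564304,-0.9995065604,0.9980267284
17.5,1.5,-1,1
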