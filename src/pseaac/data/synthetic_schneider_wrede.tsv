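synthetic_schneider_wrede	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.000000	0.230321	0.569852	0.607184	0.562680	0.111435	0.493881	0.349848	0.693603	0.325688	0.409271	0.413736	0.214293	0.491932	0.944016	0.214304	0.243376	0.235229	0.828406	0.647437
C	0.230321	0.000000	0.499983	0.508480	0.382547	0.327305	0.278562	0.249564	0.591308	0.192313	0.202769	0.265612	0.117483	0.315509	0.806916	0.200369	0.096008	0.173504	0.619659	0.423744
D	0.569852	0.499983	0.000000	0.099032	0.760218	0.577712	0.417810	0.696567	0.154986	0.653864	0.569313	0.300860	0.400291	0.312225	0.437494	0.374789	0.414639	0.640405	0.904440	0.694009
E	0.607184	0.508480	0.099032	0.000000	0.720730	0.630106	0.385906	0.683004	0.156684	0.642789	0.541340	0.316129	0.421120	0.300697	0.413597	0.418759	0.433141	0.642593	0.846240	0.644895
F	0.562680	0.382547	0.760218	0.720730	0.000000	0.673350	0.396110	0.242026	0.817735	0.240334	0.201868	0.544934	0.476560	0.525831	0.969198	0.574269	0.458293	0.338337	0.288245	0.220472
G	0.111435	0.327305	0.577712	0.630106	0.673350	0.000000	0.572410	0.459426	0.707391	0.436970	0.513872	0.460947	0.283354	0.547629	0.965972	0.244097	0.316067	0.345780	0.936707	0.750024
H	0.493881	0.278562	0.417810	0.385906	0.396110	0.572410	0.000000	0.426429	0.442085	0.371180	0.235557	0.193333	0.292466	0.136645	0.591016	0.353696	0.257338	0.415000	0.510998	0.288885
I	0.349848	0.249564	0.696567	0.683004	0.242026	0.459426	0.426429	0.000000	0.792469	0.065972	0.201380	0.494161	0.338561	0.516935	1.000000	0.429017	0.340274	0.116517	0.529356	0.409142
K	0.693603	0.591308	0.154986	0.156684	0.817735	0.707391	0.442085	0.792469	0.000000	0.744323	0.637773	0.349146	0.507398	0.328424	0.282788	0.485888	0.506694	0.745022	0.916957	0.710665
L	0.325688	0.192313	0.653864	0.642789	0.240334	0.436970	0.371180	0.065972	0.744323	0.000000	0.157406	0.435650	0.291035	0.459253	0.947624	0.382063	0.285025	0.098832	0.518715	0.375876
M	0.409271	0.202769	0.569313	0.541340	0.201868	0.513872	0.235557	0.201380	0.637773	0.157406	0.000000	0.352632	0.281618	0.347205	0.817993	0.379535	0.263737	0.232897	0.431677	0.251303
N	0.413736	0.265612	0.300860	0.316129	0.544934	0.460947	0.193333	0.494161	0.349146	0.435650	0.352632	0.000000	0.215116	0.094486	0.549801	0.218738	0.185188	0.436095	0.697577	0.473729
P	0.214293	0.117483	0.400291	0.421120	0.476560	0.283354	0.292466	0.338561	0.507398	0.291035	0.281618	0.215116	0.000000	0.283703	0.745984	0.101191	0.058844	0.254960	0.705149	0.499419
Q	0.491932	0.315509	0.312225	0.300697	0.525831	0.547629	0.136645	0.516935	0.328424	0.459253	0.347205	0.094486	0.283703	0.000000	0.497227	0.306554	0.252505	0.478391	0.644452	0.422492
R	0.944016	0.806916	0.437494	0.413597	0.969198	0.965972	0.591016	1.000000	0.282788	0.947624	0.817993	0.549801	0.745984	0.497227	0.000000	0.732300	0.730356	0.967295	0.990473	0.808958
S	0.214304	0.200369	0.374789	0.418759	0.574269	0.244097	0.353696	0.429017	0.485888	0.382063	0.379535	0.218738	0.101191	0.306554	0.732300	0.000000	0.122694	0.333197	0.796604	0.585373
T	0.243376	0.096008	0.414639	0.433141	0.458293	0.316067	0.257338	0.340274	0.506694	0.285025	0.263737	0.185188	0.058844	0.252505	0.730356	0.122694	0.000000	0.261380	0.675280	0.465259
V	0.235229	0.173504	0.640405	0.642593	0.338337	0.345780	0.415000	0.116517	0.745022	0.098832	0.232897	0.436095	0.254960	0.478391	0.967295	0.333197	0.261380	0.000000	0.617407	0.467044
W	0.828406	0.619659	0.904440	0.846240	0.288245	0.936707	0.510998	0.529356	0.916957	0.518715	0.431677	0.697577	0.705149	0.644452	0.990473	0.796604	0.675280	0.617407	0.000000	0.224186
Y	0.647437	0.423744	0.694009	0.644895	0.220472	0.750024	0.288885	0.409142	0.710665	0.375876	0.251303	0.473729	0.499419	0.422492	0.808958	0.585373	0.465259	0.467044	0.224186	0.000000
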