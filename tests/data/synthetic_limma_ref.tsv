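gene	logFC	t	P.Value	adj.P.Val
G000001	-0.1456183312876	-0.3655892804329	7.21335984445e-01	0.83769232975619
G000002	 0.1524224752131	 0.4487204353885	6.62007102369e-01	0.81062094167657
G000003	-0.0814840915616	-0.2719315564204	7.90515701591e-01	0.83769232975619
G000004	-0.3942652276662	-1.2896765321180	2.22604229160e-01	0.58070668476612
G000005	-1.6463897840666	-6.2781963074753	5.03313693247e-05	0.00301988215948
G000006	 0.7655137074772	 2.2692208507184	4.34841617739e-02	0.16306560665207
G000007	-0.2310423023894	-0.5332418083064	6.04062549980e-01	0.80957089774292
G000008	 0.6581512683675	 0.8659800078041	4.04281857844e-01	0.73619454604480
G000009	-0.4865345704839	-0.6322585017941	5.39637970754e-01	0.80957089774292
G000010	-0.4785443106156	-1.2329306587469	2.42315907304e-01	0.58543309165107
G000011	 0.5596395506895	 1.8905393247817	8.42516831935e-02	0.29735888185947
G000012	-1.6258239229254	-3.7955012836106	2.76587212201e-03	0.02370747533153
G000013	 0.1960434551516	 0.5592542596410	5.86760711287e-01	0.80957089774292
G000014	-0.1764579668781	-0.4660305187836	6.49934040947e-01	0.81062094167657
G000015	 0.4390096756704	 1.1730112998394	2.64616608684e-01	0.58543309165107
G000016	 0.0724630446292	 0.2777445306654	7.86159670090e-01	0.83769232975619
G000017	-1.8146121437225	-4.1569446564611	1.46770139665e-03	0.01467701396649
G000018	-1.8130209973246	-5.5216533010489	1.55963528741e-04	0.00467890586222
G000019	-1.0940809538013	-2.6037217608634	2.38369375851e-02	0.11001663500835
G000020	 0.0008767740483	 0.0032420946826	9.97468986531e-01	0.99746898653110
G000021	-0.5272723123734	-1.2141511592280	2.49138634259e-01	0.58543309165107
G000022	 0.1419424290608	 0.3931687594437	7.01416775374e-01	0.83769232975619
G000023	-0.2405548595402	-0.8652785975636	4.04650893129e-01	0.73619454604480
G000024	-0.2249563274406	-0.8417230090751	4.17176909425e-01	0.73619454604480
G000025	 0.3060326700876	 0.8627183504035	4.05999864844e-01	0.73619454604480
G000026	 1.2258422500312	 3.4705461641296	4.94310018881e-03	0.03707325141608
G000027	 0.0306498199685	 0.0999228338592	9.22133746457e-01	0.93776313199037
G000028	-0.2438068585759	-0.5918857371759	5.65430997494e-01	0.80957089774292
G000029	 1.8670454025430	 3.0366622239507	1.08488559756e-02	0.06509313585372
G000030	-0.2211157792017	-0.7266519901122	4.82031104577e-01	0.80338517429497
G000031	-0.5458511207480	-1.7071376453904	1.14739080249e-01	0.36233393762927
G000032	 0.3893398012327	 1.1833411346957	2.60661019833e-01	0.58543309165107
G000033	 0.8127966059881	 2.7963936907172	1.68001275707e-02	0.08400063785333
G000034	 0.9813387438617	 1.3405878480781	2.06046453608e-01	0.57672096984079
G000035	-0.0788076959277	-0.2648828587093	7.95807713268e-01	0.83769232975619
G000036	 0.1743839659034	 0.6539459236328	5.26062840518e-01	0.80957089774292
G000037	 0.3018887077654	 1.0413772854326	3.19190553302e-01	0.63838110660404
G000038	-0.2117744564450	-0.5609576236347	5.85636880694e-01	0.80957089774292
G000039	 0.4759122175181	 1.3235715278848	2.11464355608e-01	0.57672096984079
G000040	-2.0123207113937	-4.2092277538117	1.34080045481e-03	0.01467701396649
G000041	 0.0854330219939	 0.3250689601598	7.50991397771e-01	0.83769232975619
G000042	-0.4383039746004	-0.7915288224307	4.44723653010e-01	0.76238340515987
G000043	-0.6790545650484	-1.4813824403584	1.65492262424e-01	0.49647678727119
G000044	 0.7220662525177	 1.7653745599563	1.04123748059e-01	0.34707916019729
G000045	 0.1754330168496	 0.5972744919727	5.61949638993e-01	0.80957089774292
G000046	 1.3204247055688	 2.9369899747751	1.30069690674e-02	0.07094710400417
G000047	-0.7696227698689	-2.3486548163772	3.77387410502e-02	0.15095496420080
G000048	-0.0992666966830	-0.3045876571486	7.66145074824e-01	0.83769232975619
G000049	-0.1768829783285	-0.5285985377217	6.07178173307e-01	0.80957089774292
G000050	-0.2150338229846	-0.4674542995260	6.48945580676e-01	0.81062094167657
G000051	-1.4628129140087	-4.9460562617302	3.89157410274e-04	0.00583736115410
G000052	 0.1847458187773	 0.5958758019744	5.62852119548e-01	0.80957089774292
G000053	-0.0519601559783	-0.1900302507094	8.52612617421e-01	0.88201305250497
G000054	 0.5357372095535	 1.1188194210509	2.86140031264e-01	0.59201385778779
G000055	 0.0935911596015	 0.2656464996913	7.95233867029e-01	0.83769232975619
G000056	-0.6448187533403	-2.4292895507630	3.26576868525e-02	0.13996151508197
G000057	-1.7587590157883	-5.1538978890891	2.78224042557e-04	0.00556448085114
G000058	 1.1064185860490	 3.2952170706003	6.78393298886e-03	0.04522621992574
G000059	 0.1613941235836	 0.4493814874763	6.61544179739e-01	0.81062094167657
G000060	-0.3684866015644	-1.1509990938874	2.73202109437e-01	0.58543309165107
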