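node_id	node_label	network_label
n001	VIS_01	VIS
n002	VIS_02	VIS
n003	VIS_03	VIS
n004	VIS_04	VIS
n005	VIS_05	VIS
n006	VIS_06	VIS
n007	VIS_07	VIS
n008	VIS_08	VIS
n009	VIS_09	VIS
n010	VIS_10	VIS
n011	VIS_11	VIS
n012	VIS_12	VIS
n013	VIS_13	VIS
n014	VIS_14	VIS
n015	VIS_15	VIS
n016	VIS_16	VIS
n017	VIS_17	VIS
n018	VIS_18	VIS
n019	VIS_19	VIS
n020	VIS_20	VIS
n021	VIS_21	VIS
n022	VIS_22	VIS
n023	VIS_23	VIS
n024	VIS_24	VIS
n025	VIS_25	VIS
n026	VIS_26	VIS
n027	VIS_27	VIS
n028	VIS_28	VIS
n029	VIS_29	VIS
n030	VIS_30	VIS
n031	SMN_01	SMN
n032	SMN_02	SMN
n033	SMN_03	SMN
n034	SMN_04	SMN
n035	SMN_05	SMN
n036	SMN_06	SMN
n037	SMN_07	SMN
n038	SMN_08	SMN
n039	SMN_09	SMN
n040	SMN_10	SMN
n041	SMN_11	SMN
n042	SMN_12	SMN
n043	SMN_13	SMN
n044	SMN_14	SMN
n045	SMN_15	SMN
n046	SMN_16	SMN
n047	SMN_17	SMN
n048	SMN_18	SMN
n049	SMN_19	SMN
n050	SMN_20	SMN
n051	SMN_21	SMN
n052	SMN_22	SMN
n053	SMN_23	SMN
n054	SMN_24	SMN
n055	SMN_25	SMN
n056	SMN_26	SMN
n057	SMN_27	SMN
n058	SMN_28	SMN
n059	SMN_29	SMN
n060	SMN_30	SMN
n061	SMN_31	SMN
n062	SMN_32	SMN
n063	SMN_33	SMN
n064	SMN_34	SMN
n065	SMN_35	SMN
n066	SMN_36	SMN
n067	DAN_01	DAN
n068	DAN_02	DAN
n069	DAN_03	DAN
n070	DAN_04	DAN
n071	DAN_05	DAN
n072	DAN_06	DAN
n073	DAN_07	DAN
n074	DAN_08	DAN
n075	DAN_09	DAN
n076	DAN_10	DAN
n077	DAN_11	DAN
n078	DAN_12	DAN
n079	DAN_13	DAN
n080	DAN_14	DAN
n081	DAN_15	DAN
n082	DAN_16	DAN
n083	DAN_17	DAN
n084	DAN_18	DAN
n085	DAN_19	DAN
n086	DAN_20	DAN
n087	DAN_21	DAN
n088	DAN_22	DAN
n089	DAN_23	DAN
n090	DAN_24	DAN
n091	DAN_25	DAN
n092	DAN_26	DAN
n093	DAN_27	DAN
n094	DAN_28	DAN
n095	VAN_01	VAN
n096	VAN_02	VAN
n097	VAN_03	VAN
n098	VAN_04	VAN
n099	VAN_05	VAN
n100	VAN_06	VAN
n101	VAN_07	VAN
n102	VAN_08	VAN
n103	VAN_09	VAN
n104	VAN_10	VAN
n105	VAN_11	VAN
n106	VAN_12	VAN
n107	VAN_13	VAN
n108	VAN_14	VAN
n109	VAN_15	VAN
n110	VAN_16	VAN
n111	VAN_17	VAN
n112	VAN_18	VAN
n113	VAN_19	VAN
n114	VAN_20	VAN
n115	VAN_21	VAN
n116	VAN_22	VAN
n117	VAN_23	VAN
n118	VAN_24	VAN
n119	VAN_25	VAN
n120	VAN_26	VAN
n121	LIM_01	LIM
n122	LIM_02	LIM
n123	LIM_03	LIM
n124	LIM_04	LIM
n125	LIM_05	LIM
n126	LIM_06	LIM
n127	LIM_07	LIM
n128	LIM_08	LIM
n129	LIM_09	LIM
n130	LIM_10	LIM
n131	LIM_11	LIM
n132	LIM_12	LIM
n133	LIM_13	LIM
n134	LIM_14	LIM
n135	LIM_15	LIM
n136	LIM_16	LIM
n137	LIM_17	LIM
n138	LIM_18	LIM
n139	LIM_19	LIM
n140	LIM_20	LIM
n141	LIM_21	LIM
n142	LIM_22	LIM
n143	LIM_23	LIM
n144	LIM_24	LIM
n145	FPN_01	FPN
n146	FPN_02	FPN
n147	FPN_03	FPN
n148	FPN_04	FPN
n149	FPN_05	FPN
n150	FPN_06	FPN
n151	FPN_07	FPN
n152	FPN_08	FPN
n153	FPN_09	FPN
n154	FPN_10	FPN
n155	FPN_11	FPN
n156	FPN_12	FPN
n157	FPN_13	FPN
n158	FPN_14	FPN
n159	FPN_15	FPN
n160	FPN_16	FPN
n161	FPN_17	FPN
n162	FPN_18	FPN
n163	FPN_19	FPN
n164	FPN_20	FPN
n165	FPN_21	FPN
n166	FPN_22	FPN
n167	FPN_23	FPN
n168	FPN_24	FPN
n169	FPN_25	FPN
n170	FPN_26	FPN
n171	FPN_27	FPN
n172	FPN_28	FPN
n173	FPN_29	FPN
n174	FPN_30	FPN
n175	DMN_01	DMN
n176	DMN_02	DMN
n177	DMN_03	DMN
n178	DMN_04	DMN
n179	DMN_05	DMN
n180	DMN_06	DMN
n181	DMN_07	DMN
n182	DMN_08	DMN
n183	DMN_09	DMN
n184	DMN_10	DMN
n185	DMN_11	DMN
n186	DMN_12	DMN
n187	DMN_13	DMN
n188	DMN_14	DMN
n189	DMN_15	DMN
n190	DMN_16	DMN
n191	DMN_17	DMN
n192	DMN_18	DMN
n193	DMN_19	DMN
n194	DMN_20	DMN
n195	DMN_21	DMN
n196	DMN_22	DMN
n197	DMN_23	DMN
n198	DMN_24	DMN
n199	DMN_25	DMN
n200	DMN_26	DMN
n201	DMN_27	DMN
n202	DMN_28	DMN
n203	DMN_29	DMN
n204	DMN_30	DMN
n205	DMN_31	DMN
n206	DMN_32	DMN
n207	DMN_33	DMN
n208	DMN_34	DMN
n209	DMN_35	DMN
n210	DMN_36	DMN
n211	SUB_01	SUB
n212	SUB_02	SUB
n213	SUB_03	SUB
n214	SUB_04	SUB
n215	SUB_05	SUB
n216	SUB_06	SUB
n217	SUB_07	SUB
n218	SUB_08	SUB
n219	SUB_09	SUB
n220	SUB_10	SUB
n221	SUB_11	SUB
n222	SUB_12	SUB
n223	SUB_13	SUB
n224	SUB_14	SUB
n225	SUB_15	SUB
n226	SUB_16	SUB
n227	SUB_17	SUB
n228	SUB_18	SUB
n229	SUB_19	SUB
n230	SUB_20	SUB
n231	SUB_21	SUB
n232	SUB_22	SUB
n233	SUB_23	SUB
n234	SUB_24	SUB
n235	SUB_25	SUB
n236	SUB_26	SUB
n237	SUB_27	SUB
n238	SUB_28	SUB
n239	SUB_29	SUB
n240	SUB_30	SUB
n241	SUB_31	SUB
n242	SUB_32	SUB
n243	SUB_33	SUB
n244	SUB_34	SUB
n245	SUB_35	SUB
n246	SUB_36	SUB
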