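TP53_INACTIVATION	literature_set	CDC20	PLK1	CENPA	KIF2C
CIN_SIGNATURE	synthetic_placeholder	CINsyn01	CINsyn02	CINsyn03	CINsyn04	CINsyn05	CINsyn06	CINsyn07	CINsyn08	CINsyn09	CINsyn10	CINsyn11	CINsyn12	CINsyn13	CINsyn14	CINsyn15	CINsyn16	CINsyn17	CINsyn18	CINsyn19	CINsyn20	CINsyn21	CINsyn22	CINsyn23	CINsyn24	CINsyn25
PI3K_MTOR_CMAP_UP	synthetic_placeholder	SKP2	PIMTsyn001	PIMTsyn002	PIMTsyn003	PIMTsyn004	PIMTsyn005	PIMTsyn006	PIMTsyn007	PIMTsyn008	PIMTsyn009	PIMTsyn010	PIMTsyn011	PIMTsyn012	PIMTsyn013	PIMTsyn014	PIMTsyn015	PIMTsyn016	PIMTsyn017	PIMTsyn018	PIMTsyn019	PIMTsyn020	PIMTsyn021	PIMTsyn022	PIMTsyn023	PIMTsyn024	PIMTsyn025	PIMTsyn026	PIMTsyn027	PIMTsyn028	PIMTsyn029	PIMTsyn030	PIMTsyn031	PIMTsyn032	PIMTsyn033	PIMTsyn034	PIMTsyn035	PIMTsyn036	PIMTsyn037	PIMTsyn038	PIMTsyn039	PIMTsyn040	PIMTsyn041	PIMTsyn042	PIMTsyn043	PIMTsyn044	PIMTsyn045	PIMTsyn046	PIMTsyn047	PIMTsyn048	PIMTsyn049	PIMTsyn050	PIMTsyn051	PIMTsyn052	PIMTsyn053	PIMTsyn054	PIMTsyn055	PIMTsyn056	PIMTsyn057	PIMTsyn058	PIMTsyn059	PIMTsyn060	PIMTsyn061	PIMTsyn062	PIMTsyn063	PIMTsyn064	PIMTsyn065	PIMTsyn066	PIMTsyn067	PIMTsyn068	PIMTsyn069	PIMTsyn070	PIMTsyn071	PIMTsyn072	PIMTsyn073	PIMTsyn074	PIMTsyn075	PIMTsyn076	PIMTsyn077	PIMTsyn078	PIMTsyn079	PIMTsyn080	PIMTsyn081	PIMTsyn082	PIMTsyn083	PIMTsyn084	PIMTsyn085	PIMTsyn086	PIMTsyn087	PIMTsyn088	PIMTsyn089	PIMTsyn090	PIMTsyn091	PIMTsyn092	PIMTsyn093	PIMTsyn094	PIMTsyn095	PIMTsyn096	PIMTsyn097	PIMTsyn098	PIMTsyn099	PIMTsyn100	PIMTsyn101	PIMTsyn102	PIMTsyn103	PIMTsyn104	PIMTsyn105	PIMTsyn106	PIMTsyn107	PIMTsyn108	PIMTsyn109	PIMTsyn110	PIMTsyn111	PIMTsyn112	PIMTsyn113	PIMTsyn114	PIMTsyn115	PIMTsyn116	PIMTsyn117	PIMTsyn118	PIMTsyn119	PIMTsyn120	PIMTsyn121	PIMTsyn122	PIMTsyn123	PIMTsyn124	PIMTsyn125	PIMTsyn126	PIMTsyn127	PIMTsyn128	PIMTsyn129	PIMTsyn130	PIMTsyn131	PIMTsyn132	PIMTsyn133
CYTOLYTIC_ACTIVITY	literature_set	GZMA	PRF1
B_CELL_SIGNATURE	literature_set	CD19	MS4A1	CD79A	CD79B	BLK
CD8_T_CELL	literature_set	CD8A	CD8B	GZMK
NK_CELL	literature_set	NCR1	KLRD1	NKG7
IFN_ALPHA_RESPONSE	synthetic_placeholder	IFNAsyn01	IFNAsyn02	IFNAsyn03	IFNAsyn04	IFNAsyn05	IFNAsyn06	IFNAsyn07	IFNAsyn08	IFNAsyn09	IFNAsyn10	IFNAsyn11	IFNAsyn12	IFNAsyn13	IFNAsyn14	IFNAsyn15	IFNAsyn16	IFNAsyn17	IFNAsyn18	IFNAsyn19	IFNAsyn20
IFN_GAMMA_RESPONSE	synthetic_placeholder	IFNGsyn01	IFNGsyn02	IFNGsyn03	IFNGsyn04	IFNGsyn05	IFNGsyn06	IFNGsyn07	IFNGsyn08	IFNGsyn09	IFNGsyn10	IFNGsyn11	IFNGsyn12	IFNGsyn13	IFNGsyn14	IFNGsyn15	IFNGsyn16	IFNGsyn17	IFNGsyn18	IFNGsyn19	IFNGsyn20
WNT_CTNNB1_UP	synthetic_placeholder	WNTsyn01	WNTsyn02	WNTsyn03	WNTsyn04	WNTsyn05	WNTsyn06	WNTsyn07	WNTsyn08	WNTsyn09	WNTsyn10	WNTsyn11	WNTsyn12	WNTsyn13	WNTsyn14	WNTsyn15
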