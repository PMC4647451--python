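reference	region	family	n_reference	x_used	inferior_printed	superior_printed	margin_printed	group
PNGPlants	ES	Total	2258	207	0.080	0.104		total
PNGPlants	ES	Araceae	13	7	0.289	0.770	0.184	over
PNGPlants	ES	Zingiberaceae	14	6	0.213	0.677	0.108	over
PNGPlants	ES	Marantaceae	3	2	0.194	0.932	0.090	over
PNGPlants	ES	Solanaceae	9	4	0.187	0.738	0.083	over
PNGPlants	ES	Euphorbiaceae	83	22	0.182	0.369	0.078	over
PNGPlants	ES	Convolvulaceae	13	5	0.177	0.649	0.072	over
PNGPlants	ES	Datiscaceae	1	1	0.158	0.987	0.054	over
PNGPlants	ES	Fabaceae	82	19	0.154	0.334	0.050	over
PNGPlants	ES	Gnetaceae	4	2	0.147	0.853	0.042	over
PNGPlants	ES	Davalliaceae	8	3	0.137	0.701	0.033	over
PNGPlants	ES	Lamiaceae	42	10	0.135	0.386	0.031	over
PNGPlants	ES	Anacardiaceae	18	5	0.126	0.512	0.021	over
PNGPlants	ES	Asteraceae	19	5	0.119	0.491	0.015	over
PNGPlants	ES	Menispermaceae	15	4	0.110	0.524	0.006	over
PNGPlants	ES	Piperaceae	15	4	0.110	0.524	0.006	over
PNGPlants	ES	Poaceae	106	3	0.010	0.080	0.028	under
PNGPlants	EH	Total	3549	156	0.038	0.051		total
PNGPlants	EH	Ebenaceae	2	2	0.292	0.992	0.241	over
PNGPlants	EH	Winteraceae	2	2	0.292	0.992	0.241	over
PNGPlants	EH	Acanthaceae	12	5	0.192	0.684	0.141	over
PNGPlants	EH	Hypoxidaceae	1	1	0.158	0.987	0.107	over
PNGPlants	EH	Smilacaceae	7	3	0.157	0.755	0.106	over
PNGPlants	EH	Plantaginaceae	5	2	0.118	0.777	0.067	over
PNGPlants	EH	Lamiaceae	21	5	0.107	0.454	0.056	over
PNGPlants	EH	Araliaceae	17	4	0.097	0.476	0.046	over
PNGPlants	EH	Commelinaceae	2	1	0.094	0.906	0.043	over
PNGPlants	EH	Elaeagnaceae	2	1	0.094	0.906	0.043	over
PNGPlants	EH	Actinidiaceae	14	3	0.078	0.481	0.027	over
PNGPlants	EH	Asteraceae	103	13	0.076	0.204	0.024	over
PNGPlants	EH	Bignoniaceae	3	1	0.068	0.806	0.016	over
PNGPlants	EH	Casuarinaceae	3	1	0.068	0.806	0.016	over
PNGPlants	EH	Lecythidaceae	3	1	0.068	0.806	0.016	over
PNGPlants	EH	Symplocaceae	3	1	0.068	0.806	0.016	over
PNGPlants	EH	Onagraceae	9	2	0.067	0.556	0.016	over
PNGPlants	EH	Theaceae	9	2	0.067	0.556	0.016	over
PNGPlants	EH	Begoniaceae	10	2	0.060	0.518	0.009	over
PNGPlants	EH	Balsaminaceae	4	1	0.053	0.716	0.002	over
PNGPlants	EH	Caprifoliaceae	4	1	0.053	0.716	0.002	over
PNGPlants	EH	Icacinaceae	4	1	0.053	0.716	0.002	over
PNGPlants	EH	Oxalidaceae	4	1	0.053	0.716	0.002	over
PNGPlants	EH	Selaginellaceae	4	1	0.053	0.716	0.002	over
PNGPlants	EH	Usneaceae	4	1	0.053	0.716	0.002	over
PNGPlants	EH	Orchidaceae	191	1	0.001	0.029	-0.009	under
PNGPlants	BV	Total	1524	154	0.087	0.117		total
PNGPlants	BV	Verbenaceae	3	3	0.398	0.994	0.280	over
PNGPlants	BV	Musaceae	2	2	0.292	0.992	0.175	over
PNGPlants	BV	Zingiberaceae	19	9	0.272	0.685	0.155	over
PNGPlants	BV	Gnetaceae	3	2	0.194	0.932	0.077	over
PNGPlants	BV	Arecaceae	19	7	0.191	0.592	0.074	over
PNGPlants	BV	Marattiaceae	6	3	0.184	0.816	0.067	over
PNGPlants	BV	Caricaceae	1	1	0.158	0.987	0.041	over
PNGPlants	BV	Xanthorrhoeaceae	1	1	0.158	0.987	0.041	over
PNGPlants	BV	Leeaceae	4	2	0.147	0.853	0.029	over
PNGPlants	BV	Fabaceae	53	12	0.135	0.356	0.018	over
PNGPlants	BV	Thelypteridaceae	9	3	0.122	0.652	0.004	over
PNGPlants	BV	Malvaceae	30	7	0.119	0.411	0.001	over
PNGPlants	BV	Orchidaceae	74	1	0.003	0.072	-0.015	under
TMDB	ES	Total	1176	203	0.152	0.195		total
TMDB	ES	Convolvulaceae	6	5	0.421	0.963	0.226	over
TMDB	ES	Arecaceae	10	7	0.390	0.891	0.195	over
TMDB	ES	Marantaceae	2	2	0.292	0.992	0.097	over
TMDB	ES	Apocynaceae	25	9	0.202	0.557	0.007	over
TMDB	ES	Verbenaceae	22	0	0.001	0.148	-0.004	under
TMDB	EH	Total	1176	147	0.107	0.145		total
TMDB	EH	Monimiaceae	2	2	0.292	0.992	0.147	over
TMDB	EH	Plantaginaceae	2	2	0.292	0.992	0.147	over
TMDB	EH	Winteraceae	2	2	0.292	0.992	0.147	over
TMDB	EH	Melastomataceae	7	4	0.245	0.843	0.100	over
TMDB	EH	Asparagaceae	5	3	0.223	0.882	0.078	over
TMDB	EH	Smilacaceae	5	3	0.223	0.882	0.078	over
TMDB	EH	Onagraceae	3	2	0.194	0.932	0.049	over
TMDB	EH	Pittosporaceae	3	2	0.194	0.932	0.049	over
TMDB	EH	Asteraceae	47	13	0.170	0.418	0.024	over
TMDB	EH	Phyllanthaceae	1	1	0.158	0.987	0.013	over
TMDB	EH	Caryophyllaceae	1	1	0.158	0.987	0.013	over
TMDB	EH	Chloranthoceae	1	1	0.158	0.987	0.013	over
TMDB	EH	Elaegnaceae	1	1	0.158	0.987	0.013	over
TMDB	EH	Oleaceae	1	1	0.158	0.987	0.013	over
TMDB	EH	Polygalaceae	1	1	0.158	0.987	0.013	over
TMDB	EH	Tiliaceae	1	1	0.158	0.987	0.013	over
TMDB	EH	Proteaceae	4	2	0.147	0.853	0.001	over
TMDB	EH	Euphorbiaceae	88	3	0.012	0.095	-0.012	under
TMDB	BV	Total	1177	146	0.106	0.144		total
TMDB	BV	Arecaceae	10	7	0.390	0.891	0.246	over
TMDB	BV	Leeaceae	2	2	0.292	0.992	0.148	over
TMDB	BV	Rhizophoraceae	2	2	0.292	0.992	0.148	over
TMDB	BV	Thelypteridaceae	5	3	0.223	0.882	0.079	over
TMDB	BV	Zingiberaceae	23	9	0.221	0.594	0.077	over
TMDB	BV	Malvaceae	17	7	0.215	0.643	0.071	over
TMDB	BV	Salicaceae	1	1	0.158	0.987	0.014	over
TMDB	BV	Pteridaceae	1	1	0.158	0.987	0.014	over
TMDB	BV	Scrophulariaceae	1	1	0.158	0.987	0.014	over
TMDB	BV	Marattiaceae	7	3	0.157	0.755	0.013	over
TMDB	BV	Moraceae	38	10	0.150	0.421	0.006	over
TMDB	BV	Gnetaceae	4	2	0.147	0.853	0.003	over
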