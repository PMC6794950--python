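species	sample_id	group	matK	rbcL	trnH_psbA	ITS
Pulsatilla_alba	101	ingroup	MK341992	MK341971	MK341913	MK341853
Pulsatilla_alpina	104	ingroup	MK341987	MK341970	MK341914	MK341852
Pulsatilla_ambigua	107	ingroup	MK342022	MK341964	MK341895	MK341821
Pulsatilla_ambigua	108	ingroup	MK342021	MK341963	MK341894	MK341803
Pulsatilla_ambigua	109	ingroup	MK342020	MK341962	MK341893	MK341820
Pulsatilla_ambigua	175	ingroup	MK342019	MK341961	MK341892	MK341823
Pulsatilla_ambigua	189	ingroup	MK342018	MK341960	MK341891	MK341822
Pulsatilla_camanella	111	ingroup	MK341985	MK341968	MK341873	MK341819
Pulsatilla_camanella	112	ingroup	MK341984	MK341967	MK341872	MK341818
Pulsatilla_camanella	113	ingroup	MK341983	MK341966	MK341871	MK341817
Pulsatilla_camanella	114	ingroup	MK341982	MK341965	MK341870	MK341816
Pulsatilla_cernua	115	ingroup	MK342016	MK341929	MK341898	MK341836
Pulsatilla_cernua	116	ingroup	MK342015	MK341928	MK341897	MK341834
Pulsatilla_cernua	176	ingroup	MK342014	MK341927	MK341877	MK341833
Pulsatilla_cernua	177	ingroup	MK342013	MK341926	MK341876	MK341835
Pulsatilla_cernua	190	ingroup	MK342012	MK341925	MK341896	MK341832
Pulsatilla_chinensis	119	ingroup	MK342028	MK341934	MK341869	MK341824
Pulsatilla_chinensis	121	ingroup	MK342027	MK341933	MK341890	MK341827
Pulsatilla_chinensis	122	ingroup	MK342026	MK341932	MK341875	MK341826
Pulsatilla_chinensis	178	ingroup	MK342024	MK341930	MK341874	MK341825
Pulsatilla_dahurica	128	ingroup	MK342025	MK341931	MK341889	MK34183
Pulsatilla_dahurica	129	ingroup	MK342011	MK341959	MK341867	MK341842
Pulsatilla_dahurica	130	ingroup	MK342010	MK341958	MK341866	MK341841
Pulsatilla_dahurica	131	ingroup	MK342009	MK341957	MK341865	MK341840
Pulsatilla_dahurica	174	ingroup	MK342008	MK341951	MK341864	MK341839
Pulsatilla_grandis	132	ingroup	MK342023	MK341956	MK341912	MK341849
Pulsatilla_hirsutissima	133	ingroup	MK341999	MK341940	MK341900	MK341848
Pulsatilla_kostyczewii	135	ingroup	MK341979	MK341922	MK341863	MK341802
Pulsatilla_latifolia	136	ingroup	MK341998	MK341941	MK341911	MK341828
Pulsatilla_ludoviciana	137	ingroup	MK341997	MK341939	MK341899	MK341847
Pulsatilla_occidentalis	145	ingroup	MK341986	MK341969	MK341868	MK341851
Pulsatilla_patens_subsp._multifida	146	ingroup	MK341995	MK341938	MK341910	MK341846
Pulsatilla_patens_subsp._multifida	147	ingroup	MK341994	MK341937	MK341909	MK341845
Pulsatilla_patens_subsp._multifida	179	ingroup	MK341993	MK341936	MK341908	MK341844
Pulsatilla_patens_subsp._multifida	180	ingroup	MK341988	MK341935	MK341907	MK341843
Pulsatilla_patens	148	ingroup	MK341991	MK341955	MK341903	MK341838
Pulsatilla_patens	149	ingroup	MK341996	MK341954	MK341902	MK341829
Pulsatilla_patens	150	ingroup	MK341990	MK341953	MK341901	MK341837
Pulsatilla_patens	151	ingroup	MK341989	MK341952	MK341878	MK341830
Pulsatilla_sukaczevii	181	ingroup	MK341981	MK341924	MK341888	MK341815
Pulsatilla_sukaczevii	182	ingroup	-	-	MK341887	MK341814
Pulsatilla_sukaczevii	187	ingroup	-	-	MK341886	MK341813
Pulsatilla_sukaczevii	188	ingroup	MK341980	MK341923	MK341885	MK341812
Pulsatilla_tenuiloba	159	ingroup	MK342007	MK341950	MK341906	MK341808
Pulsatilla_tenuiloba	160	ingroup	MK342006	MK341949	MK341884	MK341810
Pulsatilla_tenuiloba	183	ingroup	MK342002	MK341948	MK341883	MK341807
Pulsatilla_tenuiloba	184	ingroup	MK342005	MK341947	MK341882	MK341806
Pulsatilla_turczaninovii	161	ingroup	MK342004	MK341946	MK341881	MK341811
Pulsatilla_turczaninovii	162	ingroup	MK342003	MK341945	MK341905	MK341809
Pulsatilla_turczaninovii	185	ingroup	MK342001	MK341944	MK341880	MK341805
Pulsatilla_turczaninovii	186	ingroup	MK342000	MK341943	MK341879	MK341804
Pulsatilla_vulgaris	166	ingroup	MK342017	MK341942	MK341904	MK341850
Anemone_reflexa	167	outgroup	MK341978	MK341921	MK341861	MK341854
Anemone_vitifolia	169	outgroup	MK341973	MK341917	MK341862	MK341855
Anemone_demissa	168	outgroup	MK341972	MK341915	MK341856	-
Clematis_hexapetala	170	outgroup	MK341976	MK341918	MK341860	MK341800
Clematis_tangutica	171	outgroup	MK341975	MK341919	MK341859	MK341799
Hepatica_nobilis	172	outgroup	MK341977	MK341916	MK341857	-
Anemoclema_glaucifolium	173	outgroup	MK341974	MK341920	MK341858	MK341798
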