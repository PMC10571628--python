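label_id	parcel_name	lobe
1001	ctx-lh-bankssts	LTC
1002	ctx-lh-caudalanteriorcingulate	MPFC
1003	ctx-lh-caudalmiddlefrontal	LPFC
1004	ctx-lh-corpuscallosum	ignore
1005	ctx-lh-cuneus	OCC
1006	ctx-lh-entorhinal	MTC
1007	ctx-lh-fusiform	MTC
1008	ctx-lh-inferiorparietal	PC
1009	ctx-lh-inferiortemporal	LTC
1010	ctx-lh-isthmuscingulate	PC
1011	ctx-lh-lateraloccipital	OCC
1012	ctx-lh-lateralorbitofrontal	OFC
1013	ctx-lh-lingual	OCC
1014	ctx-lh-medialorbitofrontal	OFC
1015	ctx-lh-middletemporal	LTC
1016	ctx-lh-parahippocampal	MTC
1017	ctx-lh-paracentral	SMC
1018	ctx-lh-parsopercularis	LPFC
1019	ctx-lh-parsorbitalis	LPFC
1020	ctx-lh-parstriangularis	LPFC
1021	ctx-lh-pericalcarine	OCC
1022	ctx-lh-postcentral	SMC
1023	ctx-lh-posteriorcingulate	PC
1024	ctx-lh-precentral	SMC
1025	ctx-lh-precuneus	PC
1026	ctx-lh-rostralanteriorcingulate	MPFC
1027	ctx-lh-rostralmiddlefrontal	LPFC
1028	ctx-lh-superiorfrontal	MPFC
1029	ctx-lh-superiorparietal	PC
1030	ctx-lh-superiortemporal	LTC
1031	ctx-lh-supramarginal	PC
1032	ctx-lh-frontalpole	LPFC
1033	ctx-lh-temporalpole	LTC
1034	ctx-lh-transversetemporal	LTC
1035	ctx-lh-insula	ignore
2001	ctx-rh-bankssts	LTC
2002	ctx-rh-caudalanteriorcingulate	MPFC
2003	ctx-rh-caudalmiddlefrontal	LPFC
2004	ctx-rh-corpuscallosum	ignore
2005	ctx-rh-cuneus	OCC
2006	ctx-rh-entorhinal	MTC
2007	ctx-rh-fusiform	MTC
2008	ctx-rh-inferiorparietal	PC
2009	ctx-rh-inferiortemporal	LTC
2010	ctx-rh-isthmuscingulate	PC
2011	ctx-rh-lateraloccipital	OCC
2012	ctx-rh-lateralorbitofrontal	OFC
2013	ctx-rh-lingual	OCC
2014	ctx-rh-medialorbitofrontal	OFC
2015	ctx-rh-middletemporal	LTC
2016	ctx-rh-parahippocampal	MTC
2017	ctx-rh-paracentral	SMC
2018	ctx-rh-parsopercularis	LPFC
2019	ctx-rh-parsorbitalis	LPFC
2020	ctx-rh-parstriangularis	LPFC
2021	ctx-rh-pericalcarine	OCC
2022	ctx-rh-postcentral	SMC
2023	ctx-rh-posteriorcingulate	PC
2024	ctx-rh-precentral	SMC
2025	ctx-rh-precuneus	PC
2026	ctx-rh-rostralanteriorcingulate	MPFC
2027	ctx-rh-rostralmiddlefrontal	LPFC
2028	ctx-rh-superiorfrontal	MPFC
2029	ctx-rh-superiorparietal	PC
2030	ctx-rh-superiortemporal	LTC
2031	ctx-rh-supramarginal	PC
2032	ctx-rh-frontalpole	LPFC
2033	ctx-rh-temporalpole	LTC
2034	ctx-rh-transversetemporal	LTC
2035	ctx-rh-insula	ignore
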