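# Synthetic stand-in for the curated 46-variant reference collection of
# published regulatory disease variants.  Labels and RVE-scores are generated,
# not transcribed from the literature; replace with a curated file for clinical use.
variant_label	rve_score
REFVAR_001	4
REFVAR_002	4
REFVAR_003	5
REFVAR_004	6
REFVAR_005	6
REFVAR_006	8
REFVAR_007	9
REFVAR_008	9
REFVAR_009	9
REFVAR_010	9
REFVAR_011	10
REFVAR_012	11
REFVAR_013	11
REFVAR_014	12
REFVAR_015	12
REFVAR_016	12
REFVAR_017	13
REFVAR_018	13
REFVAR_019	13
REFVAR_020	13
REFVAR_021	15
REFVAR_022	15
REFVAR_023	16
REFVAR_024	17
REFVAR_025	17
REFVAR_026	17
REFVAR_027	17
REFVAR_028	18
REFVAR_029	18
REFVAR_030	18
REFVAR_031	18
REFVAR_032	18
REFVAR_033	19
REFVAR_034	19
REFVAR_035	19
REFVAR_036	19
REFVAR_037	21
REFVAR_038	21
REFVAR_039	22
REFVAR_040	24
REFVAR_041	24
REFVAR_042	25
REFVAR_043	26
REFVAR_044	27
REFVAR_045	27
REFVAR_046	30
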