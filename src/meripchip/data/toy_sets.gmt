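KERATINIZATION_LIKE	toy keratinization-like set	GSIM00000	GSIM00001	GSIM00002	GSIM00003	GSIM00004	GSIM00005	GSIM00006	GSIM00007	GSIM00008	GSIM00009	GSIM00010	CD27	GSIM00012	GSIM00013	GSIM00014	GSIM00015	GSIM00016	GSIM00017	GSIM00018	GSIM00019	GSIM00020	GSIM00021	GSIM00022	CSMD1	GSIM00024	GSIM00025	GSIM00026	GSIM00027	GSIM00028	GSIM00029	GSIM00030	GSIM00031	GSIM00032	GSIM00033	GSIM00034	GSIM00035	GSIM00036	GSIM00037	GSIM00038	GSIM00039	GSIM00040	GSIM00041	GSIM00042	GSIM00043	GSIM00044	GSIM00045	GSIM00046	GSIM00047	GSIM00048	GSIM00049
HIPPO_LIKE	toy Hippo-like set	GSIM17587	GSIM17938	GSIM18289	GSIM18640	GSIM18991	GSIM19342	GSIM19693	GSIM20044	GSIM20395	GSIM20746	GSIM21097	GSIM21448	GSIM21799	GSIM22150	GSIM22501	GSIM22852	GSIM23203	GSIM23554	GSIM23905	GSIM24256	GSIM24607	GSIM24958	GSIM25309	GSIM25660	GSIM26011	GSIM26362	GSIM26713	GSIM27064	GSIM27415	GSIM27766	GSIM28117	GSIM28468	GSIM28819	GSIM29170	GSIM29521	GSIM29872	GSIM30223	GSIM30574	GSIM30925	GSIM31276	GSIM31627	GSIM31978	GSIM32329	GSIM32680	GSIM33031	GSIM33382	GSIM33733	GSIM34084	GSIM34435	GSIM34786
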