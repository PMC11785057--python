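seq_id	avg_flip_motif	n_strong	n_weak	best_score	best_p	bubble_positive	bubble_near_5	bubble_near_10	bubble_near_20
seq00000		0	0			False			
seq00001	0.145475	2	0	11.7039	6.38962e-05	False	False	False	False
seq00002	0.144825	2	0	13.7141	6.67572e-06	True	False	True	True
seq00003	0.153962	0	2	9.21725	0.000218391	False	False	False	False
seq00004	0.182688	2	0	12.2558	2.86102e-05	False	False	False	False
seq00005	0.1325	2	0	12.2558	2.86102e-05	False	False	False	False
seq00006		0	0			False			
seq00007	0.14325	2	0	13.7141	6.67572e-06	False	False	False	False
seq00008		0	0			True			
seq00009		0	0			False			
seq00010	0.146137	0	2	7.34452	0.000759125	True	False	False	True
seq00011		0	0			False			
seq00012	0.172575	0	2	7.34452	0.000759125	False	False	False	False
seq00013		0	0			False			
seq00014	0.136162	0	2	9.21725	0.000218391	False	False	False	False
seq00015		0	0			False			
seq00016	0.13785	0	2	8.66537	0.000398636	False	False	False	False
seq00017		0	0			False			
seq00018	0.153425	0	2	8.80281	0.000295639	False	False	False	False
seq00019	0.141675	2	0	12.2558	2.86102e-05	False	False	False	False
seq00020	0.147462	2	0	13.5766	1.23978e-05	False	False	False	False
seq00021	0.14335	2	0	11.8413	5.53131e-05	False	False	False	False
seq00022	0.189238	2	0	11.8413	5.53131e-05	True	False	True	True
seq00023	0.152912	2	0	13.5766	1.23978e-05	False	False	False	False
seq00024	0.126044	0	4	8.66537	0.000398636	False	False	False	False
seq00025		0	0			False			
seq00026	0.148087	2	0	15.4493	9.53674e-07	False	False	False	False
seq00027	0.19575	0	2	8.64777	0.000432968	False	False	False	False
seq00028		0	0			True			
seq00029		0	0			False			
seq00030	0.142838	0	2	8.66537	0.000398636	False	False	False	False
seq00031	0.157038	0	2	7.34452	0.000759125	False	False	False	False
seq00032		0	0			False			
seq00033	0.150412	0	2	10.5205	0.000109673	False	False	False	False
seq00034	0.174662	0	2	8.80281	0.000295639	False	False	False	False
seq00035	0.158625	2	0	10.9349	6.96182e-05	False	False	False	False
seq00036	0.153388	2	0	10.5381	8.67844e-05	False	False	False	False
seq00037	0.129362	0	2	10.3831	0.000126839	True	False	False	True
seq00038		0	0			False			
seq00039	0.134475	2	0	13.7141	6.67572e-06	False	False	False	False
seq00040		0	0			False			
seq00041	0.146275	2	0	11.9788	3.24249e-05	False	False	False	False
seq00042	0.12795	2	0	12.8077	1.33514e-05	False	False	False	False
seq00043	0.136625	2	0	12.8077	1.33514e-05	False	False	False	False
seq00044	0.1641	2	0	11.8413	5.53131e-05	False	False	False	False
seq00045		0	0			True			
seq00046	0.1428	0	2	7.34452	0.000759125	False	False	False	False
seq00047		0	0			False			
seq00048	0.1497	2	0	11.8413	5.53131e-05	False	False	False	False
seq00049		0	0			False			
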