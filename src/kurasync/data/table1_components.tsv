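# dc_amplitude_mv=0.0
# source_length=18000
# sample_rate_hz=300.0
index	amplitude_mv	frequency_hz	initial_phase_deg	band	bin	brainwave
0	0.1301329	0.016666666666666666	-33.85678	0	1	Infra-low delta
1	0.04297128	0.03333333333333333	-128.76518	1	2	Infra-low delta
2	0.326918	0.05	-12.38239	2	3	Infra-low delta
3	0.6956973	0.11666666666666667	119.58692	3	7	Infra-low delta
4	0.8955179	0.16666666666666666	130.46331	4	10	Infra-low delta
5	0.6738796	0.3	-142.66096	5	18	Infra-low delta
6	0.4312608	0.5666666666666667	-40.54303	6	34	Delta
7	0.1357735	1.1333333333333333	-140.43473	7	68	Delta
8	0.05983521	2.3333333333333335	-164.73776	8	140	Delta
9	0.05340884	4.333333333333333	-118.39439	9	260	Theta
10	0.02188896	8.616666666666667	-16.44028	10	517	Alpha
11	0.01331891	17.833333333333332	-120.91131	11	1070	Beta
12	0.009562677	37.63333333333333	-89.89038	12	2258	Gamma
13	0.007953602	119.93333333333334	-35.71958	13	7196	Gamma
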