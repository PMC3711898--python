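statistical_analysis	parameter_x	parameter_y	significant_5pct	p_value	df	r2	f_value	correlation
Pearson correlation and Regression	Glucose cons. rate	Biomass yield	Yes	1.42E-06	35.00	0.49	33.64	-0.70
Pearson correlation and Regression	Glucose cons. rate	Growth rate	Yes	1.98E-02	35.00	0.15	5.96	0.38
Pearson correlation and Regression	Ethanol yield	Growth rate	Yes	5.72E-01	35.00	0.01	0.33	0.38
Spearman's rank correlation rho	Glucose cons. rate	Biomass yield	Yes	2.60E-06				-0.69
Spearman's rank correlation rho	Glucose cons. rate	Growth rate	Yes	3.63E-02				0.35
Spearman's rank correlation rho	Ethanol yield	Growth rate	Yes	3.63E-02				-0.10
ANOVA	Groups	Biomass yield	Yes	1.44E-14	33.00	0.87	72.01
ANOVA	Groups	Ethanol yield	Yes	4.90E-13	33.00	0.84	55.94
ANOVA	Groups	Glucose cons. rate	Yes	2.00E-05	33.00	0.52	11.88
ANOVA	Groups	Growth rate	No	7.60E-01	33.00	0.03	0.40
Kruskal-Wallis test	Groups	Biomass yield	Yes	7.14E-06	3.00		3.00
Kruskal-Wallis test	Groups	Ethanol yield	Yes	6.62E-06	3.00		3.00
Kruskal-Wallis test	Groups	Glucose cons. rate	Yes	2.13E-04	3.00		3.00
Kruskal-Wallis test	Groups	Growth rate	No	6.00E-01	3.00		3.00
Welch Two Sample t-test on Biomass yield	Group 1	Group 2	Yes	5.26E-07	11.82
Welch Two Sample t-test on Biomass yield	Group 1	Group 3	Yes	4.80E-06	9.18
Welch Two Sample t-test on Biomass yield	Group 1	Group 4	Yes	7.68E-09	14.93
Welch Two Sample t-test on Biomass yield	Group 2	Group 3	No	5.95E-02	4.07
Welch Two Sample t-test on Biomass yield	Group 2	Group 4	Yes	7.39E-04	21.00
Welch Two Sample t-test on Biomass yield	Group 3	Group 4	No	9.76E-01	5.30
Welch Two Sample t-test on Ethanol yield	Group 1	Group 2	Yes	1.46E-06	13.79
Welch Two Sample t-test on Ethanol yield	Group 1	Group 3	Yes	4.37E-04	4.79
Welch Two Sample t-test on Ethanol yield	Group 1	Group 4	Yes	3.81E-12	22.69
Welch Two Sample t-test on Ethanol yield	Group 2	Group 3	No	7.18E-02	6.04
Welch Two Sample t-test on Ethanol yield	Group 2	Group 4	Yes	1.77E-03	16.28
Welch Two Sample t-test on Ethanol yield	Group 3	Group 4	No	5.45E-01	5.29
Welch Two Sample t-test on Glucose cons. rate	Group 1	Group 2	Yes	2.03E-06	15.84
Welch Two Sample t-test on Glucose cons. rate	Group 1	Group 3	Yes	2.49E-02	3.53
Welch Two Sample t-test on Glucose cons. rate	Group 1	Group 4	Yes	7.67E-06	17.68
Welch Two Sample t-test on Glucose cons. rate	Group 2	Group 3	No	4.24E-01	3.50
Welch Two Sample t-test on Glucose cons. rate	Group 2	Group 4	Yes	1.59E-02	17.39
Welch Two Sample t-test on Glucose cons. rate	Group 3	Group 4	No	3.45E-01	7.19
Welch Two Sample t-test on Growth rate	Group 1	Group 2	No	9.97E-01	12.78
Welch Two Sample t-test on Growth rate	Group 1	Group 3	No	4.46E-01	7.33
Welch Two Sample t-test on Growth rate	Group 1	Group 4	No	5.31E-01	17.02
Welch Two Sample t-test on Growth rate	Group 2	Group 3	No	3.89E-01	3.98
Welch Two Sample t-test on Growth rate	Group 2	Group 4	No	3.67E-01	21.00
Welch Two Sample t-test on Growth rate	Group 3	Group 4	No	7.39E-01	5.10
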