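model	quantile	all_train	all_test	all_diff	age_gt_50_train	age_gt_50_test	age_gt_50_diff	males_train	males_test	males_diff	males_age_gt_50_train	males_age_gt_50_test	males_age_gt_50_diff	age_gt_50_bmi_ge_30_train	age_gt_50_bmi_ge_30_test	age_gt_50_bmi_ge_30_diff	age_gt_50_bmi_lt_30_train	age_gt_50_bmi_lt_30_test	age_gt_50_bmi_lt_30_diff	mad_quantile	mad_all
pls	0.025	0.595	0.563	0.032	0.630	0.589	0.041	0.647	0.588	0.059	0.684	0.625	0.059	0.645	0.573	0.072	0.617	0.562	0.055	0.053	
pls	0.5	0.649	0.641	0.008	0.693	0.678	0.015	0.724	0.703	0.021	0.768	0.751	0.017	0.739	0.710	0.029	0.705	0.689	0.016	0.018	0.028
pls	0.975	0.709	0.715	-0.006	0.753	0.762	-0.009	0.791	0.812	-0.021	0.844	0.859	-0.015	0.827	0.836	-0.009	0.786	0.810	-0.024	0.014	
pcr	0.025	0.586	0.566	0.020	0.613	0.592	0.020	0.630	0.589	0.041	0.659	0.623	0.036	0.560	0.545	0.015	0.597	0.564	0.032	0.027	
pcr	0.5	0.643	0.645	-0.002	0.680	0.679	0.001	0.711	0.709	0.002	0.751	0.752	-0.001	0.707	0.701	0.007	0.696	0.691	0.005	0.003	0.018
pcr	0.975	0.706	0.721	-0.015	0.745	0.763	-0.018	0.784	0.816	-0.032	0.835	0.865	-0.029	0.810	0.831	-0.020	0.780	0.817	-0.037	0.025	
log	0.025	0.665	0.512	0.153	0.799	0.528	0.271	0.758	0.472	0.286	0.830	0.412	0.418	0.700	0.481	0.219	0.666	0.476	0.190	0.256	
log	0.5	0.717	0.601	0.116	0.852	0.627	0.225	0.830	0.599	0.231	0.972	0.587	0.386	0.794	0.639	0.155	0.751	0.622	0.129	0.207	0.203
log	0.975	0.771	0.676	0.096	0.897	0.720	0.176	0.892	0.728	0.164	1.000	0.741	0.259	0.872	0.779	0.094	0.833	0.754	0.079	0.145	
sum_pls	0.025	0.538	0.501	0.038	0.572	0.539	0.033	0.580	0.527	0.052	0.623	0.556	0.068	0.583	0.468	0.115	0.539	0.474	0.065	0.062	
sum_pls	0.5	0.588	0.581	0.007	0.638	0.628	0.011	0.657	0.641	0.015	0.704	0.692	0.012	0.661	0.627	0.033	0.621	0.611	0.010	0.015	0.033
sum_pls	0.975	0.644	0.662	-0.018	0.700	0.725	-0.025	0.733	0.755	-0.021	0.780	0.809	-0.029	0.739	0.769	-0.030	0.721	0.735	-0.013	0.023	
sum_pcr	0.025	0.514	0.498	0.016	0.553	0.536	0.017	0.557	0.527	0.030	0.598	0.553	0.044	0.514	0.432	0.082	0.521	0.480	0.042	0.039	
sum_pcr	0.5	0.577	0.578	-0.001	0.630	0.625	0.005	0.648	0.640	0.008	0.691	0.689	0.003	0.611	0.604	0.008	0.616	0.615	0.000	0.004	0.023
sum_pcr	0.975	0.639	0.662	-0.023	0.695	0.723	-0.028	0.727	0.756	-0.029	0.777	0.802	-0.024	0.709	0.738	-0.030	0.719	0.745	-0.026	0.027	
sum_log	0.025	0.559	0.504	0.055	0.600	0.538	0.063	0.599	0.515	0.084	0.647	0.549	0.098	0.613	0.517	0.096	0.562	0.432	0.130	0.088	
sum_log	0.5	0.615	0.586	0.029	0.667	0.632	0.035	0.679	0.631	0.047	0.735	0.686	0.050	0.708	0.654	0.054	0.649	0.569	0.080	0.049	0.051
sum_log	0.975	0.672	0.660	0.012	0.730	0.722	0.008	0.758	0.737	0.021	0.817	0.803	0.014	0.797	0.790	0.007	0.737	0.702	0.035	0.016	
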