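# Published per-image test-set metrics of a fundus neovascularization
# segmentation study (50 test patches; "-" marks a metric whose
# denominator was zero on that image).  Used by the regression tests and
# the acceptance script for metric-identity and average-reconstruction
# checks; no pixel data from that study is available or shipped.
image	accuracy	sensitivity	specificity	precision	jaccard	dice
1	0.9926	0.7330	0.9966	0.7626	0.5968	0.7475
2	0.9928	0.5841	0.9995	0.9536	0.5680	0.7245
3	1.0000	-	1.0000	-	-	-
4	1.0000	-	1.0000	-	-	-
5	1.0000	-	1.0000	-	-	-
6	0.9930	0.4845	0.9999	0.9837	0.4806	0.6492
7	1.0000	-	1.0000	-	-	-
8	1.0000	-	1.0000	-	-	-
9	1.0000	-	1.0000	-	-	-
10	1.0000	-	1.0000	-	-	-
11	1.0000	-	1.0000	-	-	-
12	0.9960	0.9811	0.9961	0.7188	0.7090	0.8297
13	1.0000	-	1.0000	-	-	-
14	1.0000	-	1.0000	-	-	-
15	1.0000	-	1.0000	-	-	-
16	1.0000	-	1.0000	-	-	-
17	0.9828	0.6749	0.9992	0.9781	0.6649	0.7987
18	1.0000	-	1.0000	-	-	-
19	0.9879	0.7187	0.9996	0.9859	0.7114	0.8313
20	1.0000	-	1.0000	-	-	-
21	0.9841	0.9960	0.9828	0.8623	0.8593	0.9243
22	0.9964	0.9795	0.9972	0.9415	0.9233	0.9601
23	0.9961	0.9822	0.9964	0.8132	0.8014	0.8897
24	0.9920	0.8949	0.9982	0.9700	0.8708	0.9309
25	0.9968	0.9799	0.9973	0.9071	0.8905	0.9421
26	1.0000	-	1.0000	-	-	-
27	1.0000	-	1.0000	-	-	-
28	1.0000	-	1.0000	-	-	-
29	1.0000	-	1.0000	-	-	-
30	0.9995	-	0.9995	0.0000	0.0000	0.0000
31	1.0000	-	1.0000	-	-	-
32	0.9958	0.9618	0.9972	0.9356	0.9021	0.9485
33	1.0000	-	1.0000	-	-	-
34	0.9969	0.9957	0.9969	0.8915	0.8881	0.9407
35	1.0000	-	1.0000	-	-	-
36	1.0000	-	1.0000	-	-	-
37	0.9891	0.8630	0.9946	0.8747	0.7681	0.8688
38	0.9906	0.8363	0.9988	0.9744	0.8184	0.9001
39	0.9983	0.9501	0.9992	0.9606	0.9145	0.9553
40	0.9923	0.9972	0.9922	0.8004	0.7986	0.8880
41	0.9855	0.9869	0.9854	0.8585	0.8488	0.9182
42	0.9840	0.9360	0.9874	0.8422	0.7963	0.8866
43	0.9945	0.9844	0.9952	0.9311	0.9175	0.9570
44	0.9959	0.9409	0.9973	0.8925	0.8452	0.9161
45	0.9439	0.7209	0.9906	0.9417	0.6901	0.8166
46	1.0000	-	1.0000	-	-	-
47	0.9760	0.8655	0.9898	0.9137	0.8001	0.8889
48	0.9958	0.9187	0.9987	0.9643	0.8885	0.9410
49	0.9927	0.9633	0.9955	0.9523	0.9190	0.9578
50	1.0000	-	1.0000	-	-	-
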