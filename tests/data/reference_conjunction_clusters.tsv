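cluster	region	volume_mm3	extrema_value	x	y	z
1	Middle insula R	2048	0.008536732	44.3	9.2	-1.6
2	Middle insula L	1200	0.008267164	-42.2	6.2	1
3	Putamen L	1096	0.008439786	-26.8	-0.7	-0.9
4	Precentral gyrus L	792	0.005983784	-34.6	-12.9	60.5
5	Middle cingulum L	720	0.007679645	-2.9	13	34.6
6	Supplementary motor area R	704	0.006421017	0.7	1.7	68.3
7	Middle frontal gyrus L	680	0.007679653	-35.6	44.6	29.1
8	Superior parietal lobule R	680	0.008001605	41.6	-44.1	58
9	Anterior cingulum R	640	0.007679645	5.8	25	27.7
10	Putamen L	536	0.007680166	-13.9	8.4	-6.8
11	Thalamus L	520	0.006345872	-10.4	-17.9	11
12	Superior frontal gyrus L	480	0.006096084	-24.1	-2.4	65
13	Calcarine scissure R	320	0.006865089	13.7	-94.4	4
14	Putamen R	312	0.005142419	13.1	11	-2.8
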