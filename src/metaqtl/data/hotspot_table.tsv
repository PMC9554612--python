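name	chr	position_cM	ci_95	flanking_markers	n_qtls	avg_lod	avg_pve
QTLhotspot_2A	2A	246.01	15.09	Excalibur_rep_c102244_1103/BobWhite_c30988_361	2	3.50	6.60
QTLhotspot_4A	4A	114	4.12	AX-109576258/AX-110589926	2	3.25	7.00
QTLhotspot_4B	4B	196.93	1.24	wsnp_Ex_c25373_34639805/Excalibur_c23433_474	3	4.50	9.33
QTLhotspot_5D.1	5D	54.39	3.2	Xwmc818/Xcfd26/RAC875_rep_c72023	4	3.42	18.52
QTLhotspot_5D.2	5D	355.48	5.28	CAP11_c2809_169/D_contig19403_486	2	2.72	15.33
QTLhotspot_5D.3	5D	371.12	5.33	Kukri_rep_c102237_122/Excalibur_c76347_77	2	2.14	20.43
QTLhotspot_5D.4	5D	395.35	6.11	D_contig59863_627/Kukri_rep_c101289_99	2	2.75	24.78
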