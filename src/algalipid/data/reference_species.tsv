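# Reference polar lipid species of Fucus vesiculosus with observed m/z from
# high-resolution HILIC-LC-MS (mass error < 5 ppm), by class.
# table: 1 = galactolipids/sulfolipids, 2 = phospholipids, 3 = betaine lipids.
# acyl_chains: unordered chain combinations supported by MS/MS neutral losses;
# empty when no acyl-level evidence is recorded.
# One observed value ("976. 5997") carried a stray space in the source and is
# stored repaired as 976.5997 (0.5 ppm from theory).
table	observed_mz	class_code	cn	acyl_chains	adduct
1	746.5765	MGDG	32:1	18:1/14:0, 16:1/16:0	[M+NH4]+
1	768.5621	MGDG	34:4	18:4/16:0, 18:3/16:1	[M+NH4]+
1	770.5764	MGDG	34:3	18:3/16:0	[M+NH4]+
1	772.5935	MGDG	34:2	18:2/16:0, 18:1/16:1	[M+NH4]+
1	774.6074	MGDG	34:1	18:1/16:0	[M+NH4]+
1	788.5307	MGDG	36:8	18:4/18:4	[M+NH4]+
1	790.5459	MGDG	36:7	18:3/18:4	[M+NH4]+
1	792.5614	MGDG	36:6	18:3/18:3	[M+NH4]+
1	794.5772	MGDG	36:5	18:2/18:3, 20:5/16:0	[M+NH4]+
1	796.5929	MGDG	36:4	20:4/16:0, 18:2/18:2	[M+NH4]+
1	814.5449	MGDG	38:9	20:5/18:4	[M+NH4]+
1	816.5608	MGDG	38:8	20:5/18:3, 20:4/18:4	[M+NH4]+
1	818.5766	MGDG	38:7	20:5/18:2, 20:4/18:3	[M+NH4]+
1	820.5926	MGDG	38:6	20:5/18:1, 20:4/18:2	[M+NH4]+
1	822.6073	MGDG	38:5	20:4/18:1	[M+NH4]+
1	824.6235	MGDG	38:4	20:4/18:0	[M+NH4]+
1	842.5751	MGDG	40:9	20:5/20:4	[M+NH4]+
1	844.594	MGDG	40:8	20:4/20:4	[M+NH4]+
1	536.3795	MGMG	18:1		[M+NH4]+
1	530.3329	MGMG	18:4		[M+NH4]+
1	532.3488	MGMG	18:3		[M+NH4]+
1	534.3642	MGMG	18:2		[M+NH4]+
1	906.6148	DGDG	32:2	14:0/18:2	[M+NH4]+
1	908.6305	DGDG	32:1	14:0/18:1, 16:0/16:1	[M+NH4]+
1	930.6135	DGDG	34:4		[M+NH4]+
1	932.6305	DGDG	34:3	18:3/16:0	[M+NH4]+
1	934.6461	DGDG	34:2	18:2/16:0, 18:1/16:1	[M+NH4]+
1	936.6618	DGDG	34:1	18:1/16:0	[M+NH4]+
1	938.678	DGDG	34:0	18:0/16:0	[M+NH4]+
1	952.5992	DGDG	36:7	18:3/18:4	[M+NH4]+
1	954.6148	DGDG	36:6	18:3/18:3	[M+NH4]+
1	956.6305	DGDG	36:5	20:5/16:0, 18:2/18:3	[M+NH4]+
1	958.6461	DGDG	36:4	20:4/16:0, 18:2/18:2	[M+NH4]+
1	960.6623	DGDG	36:3	18:1/18:2	[M+NH4]+
1	962.678	DGDG	36:2	18:1/18:1	[M+NH4]+
1	964.6936	DGDG	36:1	18:1/18:0	[M+NH4]+
1	976.5997	DGDG	38:9	20:5/18:4	[M+NH4]+
1	978.6144	DGDG	38:8	20:5/18:3, 20:4/18:4	[M+NH4]+
1	980.6289	DGDG	38:7	20:4/18:3, 20:5/18:2	[M+NH4]+
1	982.6448	DGDG	38:6	20:4/18:2, 20:5/18:1	[M+NH4]+
1	984.6594	DGDG	38:5	20:4/18:1	[M+NH4]+
1	986.6767	DGDG	38:4	20:4/18:0	[M+NH4]+
1	672.417	DGMG	16:0		[M+NH4]+
1	692.3857	DGMG	18:4		[M+NH4]+
1	694.4014	DGMG	18:3		[M+NH4]+
1	696.417	DGMG	18:2		[M+NH4]+
1	698.4327	DGMG	18:1		[M+NH4]+
1	527.2515	SQMG	14:0		[M-H]-
1	553.2664	SQMG	16:1		[M-H]-
1	555.2829	SQMG	16:0		[M-H]-
1	577.2673	SQMG	18:3		[M-H]-
1	579.2832	SQMG	18:2		[M-H]-
1	581.2984	SQMG	18:1		[M-H]-
1	737.4495	SQDG	28:0	14:0/14:0	[M-H]-
1	763.4648	SQDG	30:1	16:0/14:1	[M-H]-
1	765.4804	SQDG	30:0	16:0/14:0	[M-H]-
1	787.4646	SQDG	32:3	18:3/14:0	[M-H]-
1	789.4804	SQDG	32:2	18:2/14:0	[M-H]-
1	791.4958	SQDG	32:1	18:1/14:0	[M-H]-
1	793.5099	SQDG	32:0	18:0/14:0	[M-H]-
1	813.4803	SQDG	34:4	18:3/16:1	[M-H]-
1	815.4958	SQDG	34:3	18:3/16:0	[M-H]-
1	817.5107	SQDG	34:2	18:2/16:0	[M-H]-
1	819.5269	SQDG	34:1	18:1/16:0	[M-H]-
1	839.4977	SQDG	36:5	20:5/16:0	[M-H]-
1	841.5106	SQDG	36:4	20:4/16:0	[M-H]-
2	730.538	PC	32:2	16:1/16:1	[M+H]+
2	756.55	PC	34:3	16:1/18:2	[M+H]+
2	758.5689	PC	34:2	16:0/18:2, 16:1/18:1	[M+H]+
2	760.5835	PC	34:1		[M+H]+
2	780.553	PC	36:5	18:2/18:3	[M+H]+
2	784.585	PC	36:3	18:1/18:2	[M+H]+
2	786.6005	PC	36:2	18:1/18:1	[M+H]+
2	804.5545	PC	38:7		[M+H]+
2	806.5683	PC	38:6		[M+H]+
2	808.5831	PC	38:5		[M+H]+
2	494.3241	LPC	16:1		[M+H]+
2	496.3392	LPC	16:0		[M+H]+
2	522.3556	LPC	18:1		[M+H]+
2	717.471	PG	32:2	16:0/16:2, 16:1/16:1	[M-H]-
2	719.4868	PG	32:1	16:1/16:0, 14:0/18:1	[M-H]-
2	721.5033	PG	32:0	16:0/16:0, 14:0/18:0	[M-H]-
2	741.4713	PG	34:4	16:1/18:3	[M-H]-
2	743.4862	PG	34:3	16:0/18:3, 16:1/18:2	[M-H]-
2	745.5018	PG	34:2	16:0/18:2	[M-H]-
2	747.5183	PG	34:1	16:1/18:0	[M-H]-
2	749.5324	PG	34:0	16:0/18:0	[M-H]-
2	769.4987	PG	36:4	16:0/20:4, 18:2/18:2	[M-H]-
2	771.516	PG	36:3	18:1/18:2	[M-H]-
2	773.5321	PG	36:2	18:1/18:1	[M-H]-
2	481.2569	LPG	16:1		[M-H]-
2	483.2733	LPG	16:0		[M-H]-
2	509.2887	LPG	18:1		[M-H]-
2	831.4984	PI	34:3	16:0/18:3	[M-H]-
2	833.5175	PI	34:2	16:0/18:2	[M-H]-
2	835.5339	PI	34:1	16:0/18:1	[M-H]-
2	837.5491	PI	34:0	16:0/18:0	[M-H]-
2	857.5196	PI	36:4	16:0/20:4	[M-H]-
2	859.5352	PI	36:3	18:0/18:3	[M-H]-
2	861.5505	PI	36:2	18:0/18:2, 18:1/18:1	[M-H]-
2	863.5674	PI	36:1	18:0/18:1	[M-H]-
2	597.306	LPI	18:1		[M-H]-
2	686.4758	PE	32:2	14:0/18:2, 16:1/16:1	[M-H]-
2	714.5067	PE	34:2	16:1/18:1	[M-H]-
2	716.5227	PE	34:1	16:0/18:1	[M-H]-
2	762.5073	PE	38:6	18:2/20:4	[M-H]-
2	764.5232	PE	38:5	18:1/20:4	[M-H]-
2	784.4918	PE	40:9	20:4/20:5	[M-H]-
2	786.5076	PE	40:8	20:4/20:4	[M-H]-
2	498.2613	LPE	20:5		[M-H]-
2	500.2779	LPE	20:4		[M-H]-
3	656.5468	DGTS	28:0	14:0/14:0	[M+H]+
3	682.5628	DGTS	30:1	14:0/16:1	[M+H]+
3	684.5787	DGTS	30:0	14:0/16:0	[M+H]+
3	704.5458	DGTS	32:4	16:0/16:4	[M+H]+
3	706.5617	DGTS	32:3	14:0/18:3, 16:0/16:3	[M+H]+
3	708.5778	DGTS	32:2	16:0/16:2	[M+H]+
3	710.5933	DGTS	32:1	14:0/18:1, 16:0/16:1	[M+H]+
3	732.5774	DGTS	34:4	16:0/18:4	[M+H]+
3	734.5932	DGTS	34:3	16:0/18:3	[M+H]+
3	736.6083	DGTS	34:2	16:0/18:2	[M+H]+
3	738.624	DGTS	34:1	16:0/18:1	[M+H]+
3	762.6248	DGTS	36:3	18:0/18:3	[M+H]+
3	764.6405	DGTS	36:2	18:0/18:2	[M+H]+
3	446.347	MGTS	14:0		[M+H]+
3	472.3632	MGTS	16:1		[M+H]+
3	474.3792	MGTS	16:0		[M+H]+
3	494.3477	MGTS	18:4		[M+H]+
3	496.3634	MGTS	18:3		[M+H]+
3	498.3796	MGTS	18:2		[M+H]+
3	500.3943	MGTS	18:1		[M+H]+
3	656.547	DGTA	28:0	14:0/14:0	[M+H]+
3	680.5433	DGTA	30:2		[M+H]+
3	682.5623	DGTA	30:1	14:0/16:1	[M+H]+
3	684.5782	DGTA	30:0	14:0/16:0	[M+H]+
3	704.5464	DGTA	32:4	14:0/18:4	[M+H]+
3	706.5625	DGTA	32:3	14:0/18:3	[M+H]+
3	708.5778	DGTA	32:2	14:0/18:2	[M+H]+
3	710.5933	DGTA	32:1	14:0/18:1, 16:0/16:1	[M+H]+
3	732.5776	DGTA	34:4	14:0/20:4	[M+H]+
3	734.5935	DGTA	34:3	14:0/20:3, 16:0/18:3	[M+H]+
3	736.6091	DGTA	34:2	14:0/20:2, 16:0/18:2	[M+H]+
3	738.6241	DGTA	34:1	16:0/18:1	[M+H]+
3	758.5925	DGTA	36:5	16:0/20:5	[M+H]+
3	760.6085	DGTA	36:4	16:0/20:4	[M+H]+
3	762.6246	DGTA	36:3	16:0/20:3	[M+H]+
3	764.6406	DGTA	36:2	18:1/18:1	[M+H]+
3	784.6084	DGTA	38:6	18:2/20:4	[M+H]+
3	786.6235	DGTA	38:5	18:1/20:4	[M+H]+
3	446.3464	MGTA	14:0		[M+H]+
3	472.3618	MGTA	16:1		[M+H]+
3	474.3777	MGTA	16:0		[M+H]+
3	494.3463	MGTA	18:4		[M+H]+
3	496.3623	MGTA	18:3		[M+H]+
3	498.3778	MGTA	18:2		[M+H]+
3	500.3941	MGTA	18:1		[M+H]+
3	520.3619	MGTA	20:5		[M+H]+
3	522.3779	MGTA	20:4		[M+H]+
3	524.3958	MGTA	20:3		[M+H]+
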