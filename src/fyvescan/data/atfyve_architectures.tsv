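protein_id	domain_name	start	end	source
AT3G14270	FYVE	175	245	curated
AT3G14270	Fab1_TCP	350	560	curated
AT3G14270	PIPKc	1440	1720	curated
AT4G33240	FYVE	30	100	curated
AT4G33240	Fab1_TCP	230	440	curated
AT4G33240	PIPKc	1140	1410	curated
AT3G43230	FYVE	190	260	curated
AT3G43230	DUF500	460	690	curated
AT1G29800	FYVE	160	230	curated
AT1G29800	DUF500	420	650	curated
AT1G61690	FYVE	40	110	curated
AT1G20110	FYVE	320	390	curated
AT5G42140	PH_PLC	30	140	curated
AT5G42140	RCC1	200	256	curated
AT5G42140	RCC1	260	316	curated
AT5G42140	RCC1	320	376	curated
AT5G42140	RCC1	380	436	curated
AT5G42140	RCC1	440	496	curated
AT5G42140	FYVE	560	630	curated
AT5G42140	DZC	980	1040	curated
AT4G14370	PH_PLC	30	140	curated
AT4G14370	RCC1	200	256	curated
AT4G14370	RCC1	260	316	curated
AT4G14370	RCC1	320	376	curated
AT4G14370	RCC1	380	436	curated
AT4G14370	FYVE	560	630	curated
AT4G14370	DZC	980	1040	curated
AT1G65920	PH_PLC	30	140	curated
AT1G65920	RCC1	200	256	curated
AT1G65920	RCC1	260	316	curated
AT1G65920	RCC1	320	376	curated
AT1G65920	RCC1	380	436	curated
AT1G65920	RCC1	440	496	curated
AT1G65920	FYVE	560	630	curated
AT1G65920	DZC	980	1040	curated
AT1G69710	PH_PLC	30	140	curated
AT1G69710	RCC1	200	256	curated
AT1G69710	RCC1	260	316	curated
AT1G69710	RCC1	320	376	curated
AT1G69710	FYVE	560	630	curated
AT1G69710	DZC	980	1040	curated
AT3G23270	PH_PLC	30	140	curated
AT3G23270	RCC1	200	256	curated
AT3G23270	RCC1	260	316	curated
AT3G23270	RCC1	320	376	curated
AT3G23270	RCC1	380	436	curated
AT3G23270	FYVE	560	630	curated
AT3G23270	DZC	980	1040	curated
AT5G12350	PH_PLC	30	140	curated
AT5G12350	RCC1	200	256	curated
AT5G12350	RCC1	260	316	curated
AT5G12350	RCC1	320	376	curated
AT5G12350	RCC1	380	436	curated
AT5G12350	RCC1	440	496	curated
AT5G12350	FYVE	560	630	curated
AT5G12350	DZC	980	1040	curated
AT3G47660	PH_PLC	30	140	curated
AT3G47660	RCC1	200	256	curated
AT3G47660	RCC1	260	316	curated
AT3G47660	RCC1	320	376	curated
AT3G47660	FYVE	560	630	curated
AT1G76950	PH_PLC	30	140	curated
AT1G76950	RCC1	200	256	curated
AT1G76950	RCC1	260	316	curated
AT1G76950	RCC1	320	376	curated
AT1G76950	RCC1	380	436	curated
AT1G76950	FYVE	560	630	curated
AT5G19420	PH_PLC	30	140	curated
AT5G19420	RCC1	200	256	curated
AT5G19420	RCC1	260	316	curated
AT5G19420	RCC1	320	376	curated
AT5G19420	RCC1	380	436	curated
AT5G19420	RCC1	440	496	curated
AT5G19420	FYVE	560	630	curated
AT5G19420	DZC	980	1040	curated
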