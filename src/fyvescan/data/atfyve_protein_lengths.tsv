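protein_id	length
AT3G14270	1757
AT4G33240	1448
AT3G43230	860
AT1G29800	800
AT1G61690	350
AT1G20110	420
AT5G42140	1050
AT4G14370	1050
AT1G65920	1050
AT1G69710	1050
AT3G23270	1050
AT5G12350	1050
AT3G47660	1050
AT1G76950	1050
AT5G19420	1050
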