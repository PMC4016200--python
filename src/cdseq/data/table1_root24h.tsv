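transcript_id	description	fold_change
Os12t0568166-01	Conserved hypothetical protein	341.43
Os05t0211700-00	-	210.16
Os08t0404900-00	Conserved hypothetical protein	170.60
Os09t0492900-00	Conserved hypothetical protein	170.46
Os01t0653300-00	VQ domain containing protein	151.31
Os01t0661750-00	Conserved hypothetical protein	142.92
Os06t0133500-00	Conserved hypothetical protein	129.63
Os06t0662550-01	Conserved hypothetical protein	108.59
Os07t0154201-00	Hypothetical gene	103.63
Os06t0147250-00	Conserved hypothetical protein	102.14
Os02t0464550-01	Conserved hypothetical protein	101.50
Os11t0495400-00	PHF5-like protein	100.00
Os04t0429050-00	AP2-EREBP	97.98
Os10t0525200-01	Cytochrome P450 family protein	93.75
Os01t0498802-01	Non-protein coding transcript	93.09
Os12t0418600-01	Hypothetical conserved gene	82.22
Os07t0162000-00	-	82.14
Os06t0146650-00	Conserved hypothetical protein	70.88
Os08t0336200-01	Hypothetical gene	70.61
Os10t0525301-00	Hypothetical gene	68.00
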