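mirna_id	direction	n_reports
hsa-let-7d-5p	high	1
hsa-let-7g-5p	high	1
hsa-miR-15a-5p	high	1
hsa-miR-21-5p	high	2
hsa-miR-29a-3p	high	1
hsa-miR-34a-5p	high	1
hsa-miR-92a-3p	high	1
hsa-miR-93-5p	high	1
hsa-miR-126-3p	high	2
hsa-miR-127-3p	high	2
hsa-miR-130a-3p	high	1
hsa-miR-136-3p	high	1
hsa-miR-140-5p	high	1
hsa-miR-142-5p	high	1
hsa-miR-143-3p	high	1
hsa-miR-150-5p	high	2
hsa-miR-181b-5p	high	1
hsa-miR-185-5p	high	1
hsa-miR-200c-3p	high	1
hsa-miR-223-3p	high	1
hsa-miR-320e	high	1
hsa-miR-331-3p	high	1
hsa-miR-370-3p	high	1
hsa-miR-374a-5p	high	1
hsa-miR-374b-5p	high	1
hsa-miR-381-3p	high	1
hsa-miR-423-5p	high	1
hsa-miR-493-5p	high	1
hsa-miR-548ax	high	1
hsa-miR-548j-5p	high	1
hsa-miR-4454	high	1
hsa-miR-4532	high	1
hsa-miR-5581-5p	high	1
hsa-miR-6076	high	1
hsa-miR-6717-5p	high	1
hsa-miR-6875-5p	high	1
hsa-miR-7975	high	1
hsa-let-7g-3p	low	1
hsa-miR-16-2-3p	low	1
hsa-miR-26a-1-3p	low	1
hsa-miR-33a-5p	low	1
hsa-miR-126-5p	low	1
hsa-miR-183-5p	low	1
hsa-miR-203a-5p	low	1
hsa-miR-369-3p	low	1
hsa-miR-450b-5p	low	1
hsa-miR-486-5p	low	1
hsa-miR-607	low	1
hsa-miR-641	low	1
hsa-miR-3065-3p	low	1
hsa-miR-3620-3p	low	1
hsa-miR-4433a-5p	low	1
hsa-miR-5187-3p	low	1
hsa-miR-6507-3p	low	1
hsa-miR-6800-3p	low	1
hsa-miR-6819-3p	low	1
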