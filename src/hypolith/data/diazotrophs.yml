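# Curated (not canonical) lineage patterns treated as putative diazotrophs.
# Matched case-insensitively against any rank of a taxon's lineage.  Edit
# freely: orders of proteobacterial nitrogen fixers plus the heterocystous
# cyanobacterial order.
patterns:
  - Burkholderiales
  - Rhizobiales
  - Rhodospirillales
  - Nostocales
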