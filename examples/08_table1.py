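"""Summary statistics of the packaged curated phage genome table."""

import json

from pmocphage import load_table1, table1_stats

table = load_table1()
print(f"{len(table)} curated genomes from {table['site'].nunique()} sites")
print(json.dumps(table1_stats(table), indent=2))
# 22 of the 27 genomes carry pmoC (18 complete); pmoC-phage genomes span
# 159,173-527,138 bp, up to 44% GC, 224-594 ORFs and up to 29 tRNAs.
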