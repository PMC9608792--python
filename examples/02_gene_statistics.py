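"""Per-gene SFS statistics (Tajima's D_NS, pi_N/pi_S) from pooled counts.

Builds a tiny sync file by hand, filters sites, and prints the
per-population gene statistics table.
"""

import pandas as pd

from polyfoot import FilterParams, filter_sites, gene_population_stats, read_sync

# one gene, four sites, one pool: two NS SNPs, one rare NS variant below the
# calling threshold, one SYN SNP
sync_text = """\
ctg1\t101\tA\t90:0:35:0:0:0
ctg1\t102\tA\t110:15:0:0:0:0
ctg1\t103\tA\t124:0:1:0:0:0
ctg1\t104\tG\t0:40:0:85:0:0
"""
with open("example_output/tiny.sync", "w") as fh:
    fh.write(sync_text)

site_classes = pd.DataFrame(
    {
        "contig": ["ctg1"] * 4,
        "pos": [101, 102, 103, 104],
        "gene_id": ["geneA"] * 4,
        "site_class": ["NS", "NS", "NS", "SYN"],
    }
)

records = read_sync("example_output/tiny.sync", pool_sizes=[400])
sites, counters = filter_sites(records, site_classes, [400], FilterParams())
print("filtered sites:")
print(sites[["pos", "site_class", "c1", "c2", "freq_hat", "is_snp"]].to_string(index=False))
print("\ncounters:", counters)

stats = gene_population_stats(sites, pool=0, min_snps=2)
print("\nper-gene statistics (population 0):")
print(stats.to_string(index=False))
print(
    "\nS counts the called non-synonymous SNPs; D_ns compares pairwise"
    "\ndiversity against the Watterson expectation (negative = excess of"
    "\nrare variants); pi_n/pi_s measure per-site class diversity."
)
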