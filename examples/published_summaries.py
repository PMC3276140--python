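"""Rework the published cohort summary tables with the package's estimators.

Uses the transcribed 18-strain summary tables bundled in
``candimap.published``: recomputes the percentage columns from the raw
counts, the occurrence-spectrum totals, and the spontaneous-mutation-rate
upper bounds from the printed unique-SNP counts.
"""

from candimap import published
from candimap.summaries import (
    mutation_rate,
    snp_percentages,
    spectrum_totals,
    unique_density_per_kb,
)

total_snps = sum(v[0] for v in published.SNP_CATEGORY_COUNTS.values())
print(f"cohort SNP total across 18 strains: {total_snps:,}")

for strain in ("106", "1363"):
    total, nc, syn, nonsyn, *_r, nonsense = published.SNP_CATEGORY_COUNTS[strain]
    pct_nc, pct_syn, pct_nonsyn, pct_nonsense = snp_percentages(
        total, nc, syn, nonsyn, nonsense
    )
    print(
        f"strain {strain}: %NC={pct_nc} %Syn={pct_syn} "
        f"%NonSyn={pct_nonsyn} %Nonsense={pct_nonsense}"
    )

spectrum = {n: v[0] for n, v in published.INDEL_OCCURRENCE_SPECTRUM.items()}
distinct, mapped = spectrum_totals(spectrum)
print(f"indels: {distinct:,} distinct events, {mapped:,} mapped across strains")

g = published.GENOME_SIZE
for strain in ("309", "106"):
    unique = published.UNIQUE_SNP_COUNTS[strain]
    print(
        f"strain {strain}: {unique} unique SNPs -> "
        f"mu <= {mutation_rate(unique, g).mu:.3g} per base, "
        f"{unique_density_per_kb(unique, g)} unique SNPs per kb"
    )

# The mutation rate is an upper bound: private variants per surveyed base in
# the strains most heavily backcrossed into the reference background.
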