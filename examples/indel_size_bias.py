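"""Indel size spectrum and its coding-sequence bias on a synthetic cohort.

Frame-breaking indels are purged from coding sequence by selection, so the
fraction of indels inside CDS is far higher for sizes that are multiples of
three. The generator emulates that; this script measures it back from the
classified calls.
"""

from candimap.cohort import build_occurrence_matrix
from candimap.effects import annotate_cohort
from candimap.simulate import CohortConfig, generate_cohort, generate_reference
from candimap.summaries import coding_fraction_by_size, indel_size_spectrum

cfg = CohortConfig(seed=7)
reference = generate_reference(cfg)
cohort = generate_cohort(reference, cfg)
effects = annotate_cohort(cohort.records, reference)
matrix = build_occurrence_matrix(cohort.records)

spectrum = indel_size_spectrum(matrix, mode="distinct")
print("distinct indel count by |size| (insertions and deletions pooled):")
for size, count in spectrum.items():
    print(f"  {size:>3}: {count}")

fractions = coding_fraction_by_size(
    [e for calls in effects.values() for e in calls]
)
print("\npercent of indels falling in coding sequence, by |size|:")
for size in sorted(fractions):
    flag = "  <- in-frame" if size % 3 == 0 else ""
    print(f"  {size:>3}: {fractions[size]:5.1f}%{flag}")

# Expect an excess of size-4 indels overall, but a coding fraction that
# peaks at sizes 3, 6, 9 ... — frame-preserving events survive in genes.
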