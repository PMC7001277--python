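"""Generate a structured collection and run the standard marker filter.

Builds a small two-population panel of inbred lines with missing data,
homoeolog heterozygote artifacts and duplicated marker profiles, then applies
the full QC chain: recode -> deduplicate -> missing filter -> MAF filter.
"""

from wheatdiv import SimulationConfig, run_standard_filter, simulate_structured_genotypes

config = SimulationConfig(
    n_populations=2, n_per_population=(40, 40), n_markers=1000,
    reference_set_size=15, fst_target=0.25, missing_rate=0.05,
    het_artifact_rate=0.08, duplicate_fraction=0.10,
    n_chromosomes=2, chromosome_length_bp=200_000_000, seed=1,
)
matrix, placements, frame, truth = simulate_structured_genotypes(config)
print(f"raw matrix: {matrix.n_accessions} accessions x {matrix.n_markers} markers "
      f"({matrix.n_missing} missing calls)")

filtered, report = run_standard_filter(matrix)
for step in report.steps:
    print(f"  {step.name:<15} {step.n_before:>5} -> {step.n_after:>5}")
print(f"filtered matrix: {filtered.n_markers} markers")

# Each line shows how many markers survive one filter; the dedup step should
# remove at least the injected duplicate profiles:
n_injected = len(truth.duplicate_groups)
n_removed = len(report.removed_by("deduplicate"))
print(f"duplicates: {n_injected} injected, {n_removed} removed by dedup")
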