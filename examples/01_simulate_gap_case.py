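"""Generate a synthetic scaffold-gap fixture.

Builds a 2 kb genomic region with a 50 bp gap between 250 bp flanks and
paired-end reads spanning the locus, then writes the files a gap-filling
run consumes (flanks FASTA, reads FASTQ) plus the ground truth.
"""

from gaplm import SimulationConfig, make_gap_case, write_gap_case

cfg = SimulationConfig(
    region_length=2000,
    gap_length=50,
    flank_length=250,
    read_length=100,
    fragment_mean=300,
    coverage_depth=50.0,
    substitution_error_rate=0.0,
    seed=7,
)
case = make_gap_case(cfg)
paths = write_gap_case(case, "scratch/example_case")

print(f"truth gap ({len(case.truth_gap)} bp): {case.truth_gap.bases}")
print(f"recruited read pairs: {len(case.reads) // 2}")
print(f"wrote: {', '.join(str(p) for p in paths.values())}")
# The recruited reads overlap the flank+gap window, so their fragments
# collectively cover the unknown gap sequence the model must learn.
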