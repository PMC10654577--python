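"""Consensus error correction of noisy long reads.

Runs orientation, V/J/C annotation, (V,C)-partitioned clustering and
consensus voting, then measures per-read error rates against the
constant-region references before and after correction.
"""

from spatialtcr import annotate_inserts, correct_inserts, emit_reads, measure_error, orient_reads, simulate_repertoire

bundle = simulate_repertoire(n_spots=64, n_clones=12, seed=3, reads_per_clone=(20, 60))
reads, _ = emit_reads(bundle)
inserts, stats = orient_reads(reads)
records = annotate_inserts(inserts, bundle.refs)
corrected, clusters = correct_inserts(inserts, records)
report = measure_error(inserts, corrected, bundle.refs)

print(f"reads in / inserts out:  {stats['reads_in']} / {stats['inserts_out']}")
print(f"clusters formed:         {len(clusters)} (planted clones: {len(bundle.clone_truths)})")
print(f"mean error before:       {100 * report.pre_mean:.2f}% +/- {100 * report.pre_sd:.2f}")
print(f"mean error after:        {100 * report.post_mean:.2f}% +/- {100 * report.post_sd:.2f}")
print(f"mean length before/after: {report.pre_mean_length:.0f} / {report.post_mean_length:.0f} nt")
# Correction should collapse the ~4.7% raw error to near zero without
# changing transcript length; one cluster per planted clone means the
# junction-aware clustering kept clones apart.
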