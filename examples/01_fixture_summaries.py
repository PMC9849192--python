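"""Summaries of the packaged 21-event table from the haploid MA experiment.

Loads the fixture of verified deletions/duplications across 37 mutation-
accumulation lines and prints the headline summary statistics.
"""

from collections import Counter

from macnv.gene_rates import genome_event_rate, summarize_lengths
from macnv.synthetic_data import table1_fixture

events, roster = table1_fixture()
ls = summarize_lengths(events)
per_line = Counter(e.line_id for e in events)
zero = sum(1 for lid, _ in roster if per_line[lid] == 0)
rates = genome_event_rate(events, roster)

print(f"events: {ls.n_del} deletions, {ls.n_dup} duplications")
print(f"mean lengths: {ls.mean_len_del:.0f} bp (del), {ls.mean_len_dup:.0f} bp (dup)")
print(f"lines with no CNV: {zero} of {len(roster)} ({100 * zero / len(roster):.0f}%)")
busiest, n_max = per_line.most_common(1)[0]
print(f"busiest line: {busiest} with {n_max} events")
print(f"per-genome rates: {rates['genome_del'].mean_mu:.2e} del/gen, "
      f"{rates['genome_dup'].mean_mu:.2e} dup/gen")
print()
print("Most lines accumulated no deletion or duplication at all over ~1000-2000")
print("generations; the per-genome rates above are the equal-weight line means.")
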