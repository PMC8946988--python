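"""Overlap of the two packaged bivalent-promoter gene lists.

The package ships the printed lists of bivalent-promoter genes regulated by
estrogen (n=53) and by the knockdown (n=36); their intersection is computed,
never stored.
"""

from bivalint import pipeline

e2_list, kd_list = pipeline.load_table2_lists()
rep = pipeline.table2_overlap(e2_list, kd_list)
print(f"estrogen-regulated bivalent genes: {rep['n_a']}")
print(f"knockdown-regulated bivalent genes: {rep['n_b']}")
print(f"overlap: {rep['n_overlap']} genes -> {', '.join(rep['overlap'])}")
# The overlap is the bivalent-promoter genes responsive to both
# perturbations; the progesterone receptor (PGR) is the headline member.
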