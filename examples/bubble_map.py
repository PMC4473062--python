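"""All-pairwise GSEA bubble map: where do reference fingerprints light up?

Extracts every cell-type fingerprint from the reference species, then tests
each for enrichment in every pair of cell types of a test species.  A cell
type of the test species that consistently wins the pairs it appears in is
the candidate homolog of the fingerprint's cell type.
"""

import crosscell as cc

data = cc.generate(cc.SyntheticSpec(seed=7))
ref = data.datasets["spA"]          # reference: fingerprints come from here
test = data.datasets["spB"]         # test species to be annotated

res = cc.run_workflow_a(ref, [test], data.orthology, fold=1.5, n_perm=500, seed=1)
grid = res.grids["spB"]
table = cc.grid_to_frame(grid)
print(table[["geneset", "class_a", "class_b", "NES", "fdr_q", "direction"]].to_string(index=False))

sig = table[table.fdr_q < 0.05]
print(f"\n{len(sig)}/{len(table)} cells significant at FDR < 0.05; "
      "each fingerprint should be enriched toward its planted homolog "
      "in every pair that involves it.")

svg = cc.render_bubbles(grid, "scratch_bubble_map.svg")
print("wrote scratch_bubble_map.svg (area ~ |NES|, opacity ~ FDR bin, color = winner)")
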