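"""Infer the colinear depth ratio and build the multi-genome alignment table.

A tetraploid and a hexaploid descendant of the same ancestor show a 2:3
depth ratio; using the tetraploid as reference, the table lists each
reference gene's colinear genes per expected subgenome of the query, with
'.' marking absences (gene loss).
"""

from wgdkit import collinearity as col
from wgdkit import depth_align as da
from wgdkit import simulate as sim

scenario = sim.Scenario(
    species_tree="(H:50,T:50);",
    wgd_events=[
        sim.WgdEvent("HEX", 3, "H", loss_prob=(0.2, 0.2, 0.2), run_p=0.6),
        sim.WgdEvent("TET", 2, "T", loss_prob=(0.2, 0.3), run_p=0.6),
    ],
    n_chromosomes=2,
    genes_per_chromosome=300,
    codons_per_gene=3,
    ks_per_myr=0.004,
    seed=5,
)
result = sim.simulate_scenario(scenario)
ann_t, ann_h = result.annotation("T"), result.annotation("H")

blocks = col.chain_blocks(result.hit_pairs("T", "H"), ann_t, ann_h)
profile = da.depth_ratio(blocks, ann_t, ann_h)
print(f"colinear depth ratio T:H = {profile.ratio[0]}:{profile.ratio[1]}")

table = da.build_alignment_table(ann_t, [(ann_h, 3, blocks)], ref_depth=1)
print(f"table columns: {table.header}")
print(table.data.head(8).to_string())
absent = table.absence_counts()
print(f"absence marks per column: {dict(absent)}")

# The 2:3 ratio reads: each tetraploid-derived region matches 3 regions in
# the hexaploid and each hexaploid region matches 2 in the tetraploid --
# the signature that the two genomes experienced different multiplications
# after their split.  Absence marks count the hexaploid's fractionation
# losses at reference-anchored positions.
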