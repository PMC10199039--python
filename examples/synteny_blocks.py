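"""Synteny block structure of classified ohnolog pairs.

Rediploidization proceeds in chromosomal blocks, so neighbouring families
share a category.  This script lays classified families on chromosomes,
calls same-category blocks, and tests whether categories cluster along each
sturgeon chromosome more than a random shuffle allows.
"""

import pandas as pd

import lorescan as ls

cfg = ls.SimConfig(n_blocks=10, genes_per_block=8, n_chrom_pairs=5, seed=6)
dataset = ls.simulate_dataset(cfg)
truth = dataset["truth"]

classified = pd.DataFrame(
    {"family_id": f.family_id, "rooted_category": f.category}
    for f in truth.families
)
quartets = {
    f.family_id: {
        "Sturgeon": list(f.genes["Sturgeon"]),
        "Paddlefish": list(f.genes["Paddlefish"]),
        "orthologs": list(f.ortholog_pairs),
    }
    for f in truth.families
}
links = ls.build_links(classified, dataset["coords"], mode="intra", quartets=quartets)
blocks = ls.detect_blocks(
    links[links["species_a"] == "Sturgeon"], min_genes=3, max_gap=1
)

print(f"{len(links)} links, {len(blocks)} sturgeon blocks:")
for b in blocks:
    print(f"  {b.chrom_a:<9} {b.category:<9} n={b.n_genes:>2}  "
          f"{b.start_a/1e3:.0f}-{b.end_a/1e3:.0f} kb")

print("\nadjacent same-category clustering per chromosome:")
stu = links[links["species_a"] == "Sturgeon"].sort_values(["chrom_a", "pos_a"])
for chrom, grp in stu.groupby("chrom_a"):
    res = ls.clustering_permutation_test(grp["rooted_category"].tolist(), 1000, seed=1)
    print(f"  {chrom}: observed {res['observed_statistic']} adjacent same-category "
          f"pairs, p = {res['p_value']:.4f}")
print("\nChromosome pairs carrying two categories give small p-values: the")
print("categories are not randomly interleaved but form contiguous blocks.")
print("Chromosomes whose blocks all share one category are degenerate (p = 1).")
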