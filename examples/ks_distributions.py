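"""Category-stratified Ks distributions from simulated coding sequences.

PostSpec ohnolog pairs diverged after speciation (young, low Ks); PreSpec
pairs diverged between the WGD and speciation (old, high Ks); cross-species
ortholog pairs diverged exactly at speciation and sit in between.  The
ordering of the three distribution modes is the corroborating signature of
a shared WGD with asynchronous rediploidization.
"""

import lorescan as ls
from lorescan.simulate import family_time_tree

cfg = ls.SimConfig(n_blocks=120, genes_per_block=1, seed=3)
truth = ls.simulate_blocks(cfg)

families = []
for i, fam in enumerate(truth.families):
    cds = ls.simulate_sequences(
        family_time_tree(fam, cfg), 200, seed=1000 + i, mode="codon",
        syn_rate=cfg.syn_rate, nonsyn_rate=cfg.nonsyn_rate,
    )
    (sa, sb), (pa, pb) = fam.genes["Sturgeon"], fam.genes["Paddlefish"]
    get = lambda sp, g: cds[f"{sp}|{g}"]
    families.append(
        ls.KsFamily(
            fam.family_id, fam.category,
            sturgeon_pair=((sa, get("Sturgeon", sa)), (sb, get("Sturgeon", sb))),
            paddlefish_pair=((pa, get("Paddlefish", pa)), (pb, get("Paddlefish", pb))),
            ortholog_pairs=tuple(
                ((sg, get("Sturgeon", sg)), (pg, get("Paddlefish", pg)))
                for sg, pg in fam.ortholog_pairs
            ) if fam.category == "PreSpec" else (),
        )
    )

records = ls.build_ks_datasets(families, max_ks=0.3)
summary = ls.ks_summary(records)
print(f"{'dataset':<16} {'n':>4} {'Q1':>6} {'median':>7} {'Q3':>6} {'mode':>6}")
for name in ("PostSpec", "PreSpecOrtholog", "PreSpec"):
    s = summary[name]
    q1, q2, q3 = s["quartiles"]
    print(f"{name:<16} {s['n']:>4} {q1:>6.3f} {q2:>7.3f} {q3:>6.3f} {s['mode']:>6.3f}")
print("\nThe modes are ordered PostSpec < ortholog < PreSpec, as expected when")
print("speciation falls inside the rediploidization window of a shared WGD.")
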