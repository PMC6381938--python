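"""Reconstruct a subject's allele set starting from one allele per family.

Simulates a subject carrying 10 genes x 2 alleles across 3 gene
families at mixed usage, then deletes the database down to a single
allele per family (the most frequently assigned one).  Iterating
detection -> acceptance (frequency-genotype 7/8 rule) -> nearest-
germline reassignment rebuilds most of the allele set, including
alleles tens of SNPs away from the seed.
"""

import novallele as nv

db = nv.random_germline_database(
    n_families=3, genes_per_family=4, alleles_per_gene=2, seed=21
)
genes = sorted(db.by_gene())
chosen = genes[:4] + genes[4:7] + genes[8:11]
usages = [(0.5, 0.5), (0.67, 0.33), (0.75, 0.25)]
genotype = {}
for i, gene in enumerate(chosen):
    names = [a.full_name for a in db.by_gene()[gene]]
    u = usages[i % 3]
    genotype[gene] = {names[0]: u[0], names[1]: u[1]}

cfg = nv.SimConfig(db=db, genotype=genotype, sequences_per_gene=2000, seed=33)
rep, _ = nv.simulate_repertoire(cfg)
rep = nv.filter_input(rep)

truth_alleles = {a for spec in genotype.values() for a in spec}
public = nv.GermlineDatabase(db[a] for a in sorted(truth_alleles))
seed_db = nv.sparse_seed_database(nv.reassign_all(rep, public), public)
print(f"seed database: {seed_db.names()}")

result = nv.iterative_inference(rep, seed_db, max_iter=10)
for state in result.history:
    print(
        f"iteration {state.iteration}: {state.n_candidates} candidates, "
        f"{len(state.accepted)} accepted, database now {state.db_size} alleles"
    )
found = {a.v_region for a in result.database}
recovered = sum(db[a].v_region in found for a in truth_alleles)
print(
    f"recovered {recovered}/{len(truth_alleles)} true alleles "
    f"({100 * recovered / len(truth_alleles):.0f}%), converged={result.converged}"
)
# Low-usage alleles are the ones that stay hidden: their sequences are a
# minority inside a shared mutation window until reassignment isolates
# them, which is why recovery improves with sequencing depth.
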