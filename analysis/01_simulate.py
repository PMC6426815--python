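"""Generate the synthetic study inputs: expression matrix over the 2x2
genotype x doxycycline design (planted template effects, low-signal rows,
annotation quirks), IP-proteomics hit tables with IgG controls, and a qPCR
Ct table. Everything is seeded and written as TSV under results/data/.
"""

from pathlib import Path

from taupattern.io import write_annotation, write_expression_matrix, write_table
from taupattern.proteome import write_hit_table
from taupattern.simulate import (
    CtSimConfig,
    ProteomeSimConfig,
    SimConfig,
    generate_annotation,
    generate_ct_table,
    generate_expression,
    generate_proteome,
)

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sim = SimConfig(n_genes=10_000, seed=SEED)
    matrix, truth = generate_expression(sim)
    write_expression_matrix(matrix, OUT / "matrix.tsv", OUT / "design.tsv")
    write_annotation(generate_annotation(truth), OUT / "annotation.tsv")
    write_table(truth, OUT / "truth.tsv", index_label="gene")
    planted = (truth["status"] == "planted").sum()
    print(
        f"expression: {len(matrix.genes)} genes x {len(matrix.samples)} samples "
        f"(cells {tuple(sim.n_per_group)}); {planted} planted DEGs "
        f"({sim.planted_fraction:.0%} per template, effect {sim.effect_size} log2, "
        f"noise sd {sim.noise_sd})"
    )

    tables, ptruth = generate_proteome(ProteomeSimConfig(), seed=SEED)
    for table in tables:
        write_hit_table(table, OUT / f"hits_{table.group}.tsv")
    write_table(ptruth, OUT / "proteome_truth.tsv", index_label="protein")
    print(f"proteome: {len(tables)} hit tables over {len(ptruth)} proteins "
          f"({int(ptruth['contaminant'].sum())} contaminants shared with IgG controls)")

    ct = generate_ct_table(
        CtSimConfig(group_fold_changes={"Control": 1.0, "Case": 2.0}, n_per_group=10),
        seed=SEED,
    )
    ct.to_csv(OUT / "ct_table.tsv", sep="\t", index=False)
    print(f"qPCR: {len(ct)} Ct records, true Case fold change 2.0")


if __name__ == "__main__":
    main()
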