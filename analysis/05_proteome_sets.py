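"""Nascent-proteome set analysis: post-search filters (>= 1 unique peptide,
ion score > 30), IgG-control subtraction, merge of the two non-transgenic
groups, Venn partitioning, and annotation-category ratios on a small
synthetic annotation-record table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from taupattern.io import write_table
from taupattern.proteome import (
    DEFAULT_CATEGORIES,
    annotation_ratio,
    combine_non_groups,
    filter_hits,
    read_hit_table,
    subtract_controls,
    venn_counts,
    venn_partition,
)

SEED = 7
ROOT = Path(__file__).resolve().parents[1] / "results"
GROUPS = ("Non_Veh", "Non_Dox", "Tg_Veh", "Tg_Dox")
IGG = ("IgG_Non", "IgG_Tg")


def synthetic_annotation_records(rng) -> pd.DataFrame:
    """Synthetic stand-in for an annotation-term table (term, group, category,
    adjusted p), with translation terms depleted in the tau group and rescued
    by doxycycline."""
    weights = {
        "Non": {"translation_ribosome": 8, "synaptic": 5, "metabolic": 5,
                "cytoskeletal": 3, "signaling": 4, "other": 3},
        "Tg_Veh": {"translation_ribosome": 2, "synaptic": 4, "metabolic": 6,
                   "cytoskeletal": 4, "signaling": 5, "other": 3},
        "Tg_Dox": {"translation_ribosome": 7, "synaptic": 5, "metabolic": 5,
                   "cytoskeletal": 3, "signaling": 4, "other": 3},
    }
    rows = []
    for group, per_cat in weights.items():
        for category, n in per_cat.items():
            for i in range(n):
                rows.append((f"{category}_{i}", group, category, float(rng.uniform(0.0, 0.09))))
    return pd.DataFrame(rows, columns=["term", "group", "category", "adjusted_p"])


def main() -> None:
    data = ROOT / "data"
    samples = [filter_hits(read_hit_table(data / f"hits_{g}.tsv", g)) for g in GROUPS]
    iggs = [read_hit_table(data / f"hits_{g}.tsv", g) for g in IGG]
    raw_total = sum(len(read_hit_table(data / f"hits_{g}.tsv", g)) for g in GROUPS)
    cleaned = subtract_controls(samples, iggs)
    print(
        f"post-search filters + IgG subtraction: {raw_total} records -> "
        f"{sum(len(t) for t in cleaned)} across {len(cleaned)} groups"
    )

    merged = combine_non_groups(cleaned)
    regions = venn_partition(merged)
    counts = venn_counts(regions)
    write_table(counts.rename_axis("region").reset_index(), ROOT / "venn_regions.tsv")
    labels = [t.group for t in merged]
    print(f"Venn over {labels}:")
    for region, n in counts.items():
        members = " + ".join(lbl for lbl, bit in zip(labels, region) if bit == "1")
        print(f"  {region} ({members}): {n}")

    records = synthetic_annotation_records(np.random.default_rng(SEED))
    ratios = annotation_ratio(records, reference_group="Non", alpha=0.1,
                              categories=DEFAULT_CATEGORIES)
    write_table(ratios, ROOT / "annotation_ratios.tsv", index_label="category")
    print("annotation-term ratios vs Non (translation depleted in Tg_Veh, rescued by dox):")
    print(ratios.round(2).to_string())


if __name__ == "__main__":
    main()
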