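"""Annotate the dose signatures by gene-set overlap.

Builds a GMT collection from the simulation's ground-truth planted blocks
plus random decoy sets, then ranks sets by upper-tail hypergeometric
overlap with each signature's full/up/down probe lists (top 20).  The
planted blocks should dominate the rankings."""

from pathlib import Path

import numpy as np
import pandas as pd

from pbsig import load_expression
from pbsig.enrichment import annotate_signature
from pbsig.formats import GeneSetCollection, save_gene_sets
from pbsig.signature import Signature

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = load_expression(OUT / "simulated" / "study.gct")
    truth = pd.read_csv(OUT / "simulated" / "study_truth.tsv", sep="\t")

    sets = {
        f"PLANTED_{cat.upper()}": {
            "description": "ground-truth planted block",
            "members": sub["probe_id"].tolist(),
        }
        for cat, sub in truth.groupby("category")
    }
    rng = np.random.default_rng(42)
    for i in range(20):
        sets[f"DECOY_{i:02d}"] = {
            "description": "random decoy set",
            "members": list(rng.choice(matrix.probe_ids, size=50, replace=False)),
        }
    collection = GeneSetCollection(sets)
    save_gene_sets(collection, OUT / "planted_collection.gmt")

    for dose in ("low", "high"):
        sig = Signature.load_tsv(OUT / f"signature_{dose}.tsv")
        results = annotate_signature(sig, collection, universe_size=matrix.n_probes, top=20)
        for part, res in results.items():
            res.save_tsv(OUT / f"enrichment_{dose}_{part}.tsv")
        best = results["up"].table.iloc[0]
        print(
            f"{dose} signature, up list: best set {best['set_name']} "
            f"(overlap {best['overlap']}/{best['set_size']}, p = {best['p_value']:.3g})"
        )


if __name__ == "__main__":
    main()
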