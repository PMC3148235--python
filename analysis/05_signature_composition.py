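"""Decompose and compare the dose signatures by direction.

Splits each signature into up/down components and counts the probes
shared between the doses: concordant-up, concordant-down, and discordant
(up at the low dose, down at the high dose).  Writes the comparison JSON
(with probe lists) under results/."""

from pathlib import Path

from pbsig.composition import compare_signatures, split_by_direction
from pbsig.signature import Signature

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sigs = {d: Signature.load_tsv(OUT / f"signature_{d}.tsv") for d in ("low", "high")}
    for dose, sig in sigs.items():
        parts = split_by_direction(sig)
        print(f"{dose} signature: {len(parts['up'])} up, {len(parts['down'])} down")
    cmp = compare_signatures(sigs["low"], sigs["high"])
    cmp.save_json(OUT / "comparison_low_vs_high.json")
    c = cmp.counts
    print(
        f"shared: {c['shared_total']} total "
        f"({c['shared_up']} up in both, {c['shared_down']} down in both, "
        f"{c['discordant']} discordant)"
    )
    discordant = cmp.discordant_up_a_down_b  # up at low dose, down at high dose
    (OUT / "discordant_low_up_high_down.txt").write_text("\n".join(discordant) + "\n")
    print(f"discordant (low-up/high-down) list of {len(discordant)} probes written")


if __name__ == "__main__":
    main()
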