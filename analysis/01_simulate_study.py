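"""Generate the synthetic two-dose lead-exposure study.

Writes the default 5000-probe, 72-sample study (control/low/high groups,
exposure + recovery bleeds, planted dose-specific probe blocks, full
reversion at recovery) as GCT/CLS/TSV under results/simulated/, together
with the ground-truth plant table."""

from pathlib import Path

import pandas as pd

from pbsig.pipeline import write_simulated_study

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    paths = write_simulated_study(OUT / "simulated", effect_size=3.0, reversion=0.0, seed=42)
    truth = pd.read_csv(paths["truth"], sep="\t")
    print(f"wrote {len(paths)} files under {OUT / 'simulated'}")
    print("planted probes per category:")
    print(truth["category"].value_counts().to_string())
    print(f"total planted: {len(truth)} (= 250 + 250 - 28)")


if __name__ == "__main__":
    main()
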