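"""Direction decomposition and overlap of dose signatures.

Each signature splits into its upregulated and downregulated components
(sign of the selection correlation).  Comparing two signatures yields the
shared probes, stratified into concordant-up, concordant-down and
discordant (opposite direction in the two signatures, reported separately
per direction — the up-in-A/down-in-B set is the input to downstream
regulatory-motif annotation).  Overlap is computed on probe identifiers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .signature import Signature

__all__ = ["SignatureComparison", "split_by_direction", "compare_signatures"]


@dataclasses.dataclass
class SignatureComparison:
    up_a: list[str]
    down_a: list[str]
    up_b: list[str]
    down_b: list[str]
    shared_up: list[str]
    shared_down: list[str]
    discordant_up_a_down_b: list[str]
    discordant_down_a_up_b: list[str]

    @property
    def discordant(self) -> list[str]:
        return sorted(self.discordant_up_a_down_b + self.discordant_down_a_up_b)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared_total": len(self.shared_up) + len(self.shared_down) + len(self.discordant),
            "shared_up": len(self.shared_up),
            "shared_down": len(self.shared_down),
            "discordant": len(self.discordant),
            "up_a": len(self.up_a),
            "down_a": len(self.down_a),
            "up_b": len(self.up_b),
            "down_b": len(self.down_b),
        }

    def save_json(self, path: str | Path) -> None:
        doc = dict(self.counts)
        doc["lists"] = {
            "shared_up": self.shared_up,
            "shared_down": self.shared_down,
            "discordant_up_a_down_b": self.discordant_up_a_down_b,
            "discordant_down_a_up_b": self.discordant_down_a_up_b,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def split_by_direction(signature: Signature) -> dict[str, list[str]]:
    """Partition a signature's probes into 'up' and 'down' lists."""
    return {"up": signature.up_probes(), "down": signature.down_probes()}


def compare_signatures(sig_a: Signature, sig_b: Signature) -> SignatureComparison:
    """Probe-level overlap of two signatures with direction concordance."""
    a = split_by_direction(sig_a)
    b = split_by_direction(sig_b)
    up_a, down_a = set(a["up"]), set(a["down"])
    up_b, down_b = set(b["up"]), set(b["down"])
    return SignatureComparison(
        up_a=sorted(up_a),
        down_a=sorted(down_a),
        up_b=sorted(up_b),
        down_b=sorted(down_b),
        shared_up=sorted(up_a & up_b),
        shared_down=sorted(down_a & down_b),
        discordant_up_a_down_b=sorted(up_a & down_b),
        discordant_down_a_up_b=sorted(down_a & up_b),
    )
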