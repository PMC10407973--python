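"""Combine predictions from several trained models into one prediction set.

Two modes: soft voting (mean score vector, then argmax) and majority
voting over hard labels.  All members must cover exactly the same pair
keys; ties resolve to the lower canonical label index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import Prediction
from .formats_io import ALL_LABELS, RelationLabel


@dataclass(frozen=True)
class EnsembleConfig:
    mode: str = "soft_vote"  # or "majority"
    n_models: int = 1

    def __post_init__(self):
        if self.mode not in ("soft_vote", "majority"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def ensemble_predict(
    member_predictions: Sequence[Sequence[Prediction]],
    cfg: EnsembleConfig = EnsembleConfig(),
) -> list[Prediction]:
    """Combine aligned member prediction lists.

    Members must be aligned on pair keys (same keys, same order after
    keying); misalignment raises with the offending keys listed.
    """
    if len(member_predictions) == 0:
        raise ValueError("no member predictions given")

    keyed: list[dict] = []
    for preds in member_predictions:
        d = {p.pair_key: p for p in preds}
        if len(d) != len(preds):
            raise ValueError("duplicate pair keys within one member")
        keyed.append(d)
    ref_keys = set(keyed[0])
    for i, d in enumerate(keyed[1:], start=2):
        if set(d) != ref_keys:
            missing = sorted(ref_keys ^ set(d))[:5]
            raise ValueError(
                f"member {i} is misaligned on pair keys, e.g. {missing}"
            )

    order = [p.pair_key for p in member_predictions[0]]
    out: list[Prediction] = []
    for key in order:
        members = [d[key] for d in keyed]
        if cfg.mode == "soft_vote":
            for m in members:
                if m.scores is None:
                    raise ValueError("soft_vote requires per-label scores")
            mean = np.mean([m.scores for m in members], axis=0)
            mean = mean / mean.sum()
            label = RelationLabel(int(np.argmax(mean)))
            out.append(Prediction(pair_key=key, label=label, scores=tuple(float(x) for x in mean)))
        else:  # majority
            votes = np.zeros(len(ALL_LABELS))
            for m in members:
                votes[int(m.label)] += 1
            label = RelationLabel(int(np.argmax(votes)))  # tie -> lower index
            scores = votes / votes.sum()
            out.append(Prediction(pair_key=key, label=label, scores=tuple(float(x) for x in scores)))
    return out
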