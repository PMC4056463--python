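"""Recall / false-positive-rate evaluation of predicted junctions.

Recall is the fraction of simulated (truth) junction loci correctly
identified; the false positive rate divides the number of wrong
predicted junctions by the number of predicted junctions; precision is
1 - FPR.  A predicted junction is correct iff a truth junction exists
with both breakpoints within ``tolerance`` nt and compatible strands;
each truth junction is matched at most once (greedy nearest-first).
Both sides are expected in canonical (normalized, flip-minimal)
coordinates, which the pipeline and the simulator produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .junctions import Junction

_CLASSES = ["regular", "strand-reversing", "long-range", "circular"]


@dataclass
class ClassStats:
    n_truth: int = 0
    n_predicted: int = 0
    n_correct: int = 0

    @property
    def recall(self) -> Optional[float]:
        return None if self.n_truth == 0 else self.n_correct / self.n_truth

    @property
    def precision(self) -> Optional[float]:
        if self.n_predicted == 0:
            return None
        return self.n_correct / self.n_predicted


@dataclass
class EvalReport:
    n_truth: int
    n_predicted: int
    n_correct: int
    n_wrong: int
    recall: Optional[float]
    fpr: Optional[float]
    precision: Optional[float]
    per_class: Dict[str, ClassStats] = field(default_factory=dict)

    def summary(self) -> str:
        def fmt(x):
            return "NA" if x is None else f"{100 * x:.2f}%"

        lines = [
            f"truth junctions:     {self.n_truth}",
            f"predicted junctions: {self.n_predicted}",
            f"correct / wrong:     {self.n_correct} / {self.n_wrong}",
            f"recall:              {fmt(self.recall)}",
            f"false positive rate: {fmt(self.fpr)}",
            f"precision:           {fmt(self.precision)}",
        ]
        for cls in _CLASSES:
            st = self.per_class.get(cls)
            if st is None or (st.n_truth == 0 and st.n_predicted == 0):
                continue
            lines.append(
                f"  {cls:<17} truth {st.n_truth:>5}  predicted {st.n_predicted:>5}"
                f"  recall {fmt(st.recall)}  precision {fmt(st.precision)}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": "all",
                "n_truth": self.n_truth,
                "n_predicted": self.n_predicted,
                "n_correct": self.n_correct,
                "recall": self.recall,
                "fpr": self.fpr,
                "precision": self.precision,
            }
        ]
        for cls, st in self.per_class.items():
            rows.append(
                {
                    "class": cls,
                    "n_truth": st.n_truth,
                    "n_predicted": st.n_predicted,
                    "n_correct": st.n_correct,
                    "recall": st.recall,
                    "fpr": None if st.precision is None else 1 - st.precision,
                    "precision": st.precision,
                }
            )
        return pd.DataFrame(rows)


TruthEntry = Tuple[Tuple[str, int, str], Tuple[str, int, str], str]


def _compatible(p: Junction, t: TruthEntry, tolerance: int) -> Optional[int]:
    """Match distance if compatible within tolerance, else None."""
    (tdc, tdp, tds), (tac, tap, tas), _cls = t
    (pdc, pdp, pds), (pac, pap, pas) = p.donor, p.acceptor
    if pdc != tdc or pac != tac:
        return None
    # canonical (flip-minimal) keys make orientation comparable even for
    # unstranded libraries
    if pds != tds or pas != tas:
        return None
    d1, d2 = abs(pdp - tdp), abs(pap - tap)
    if d1 > tolerance or d2 > tolerance:
        return None
    return d1 + d2


def match_junctions(
    predicted: Sequence[Junction],
    truth: Sequence[TruthEntry],
    tolerance: int = 0,
) -> EvalReport:
    """Score a predicted junction set against the truth catalog.

    ``truth`` entries are ``(donor, acceptor, class)`` with breakpoints
    as ``(chrom, pos, strand)``.  With an empty truth set, recall is
    reported as not applicable (None).
    """
    truth = sorted(truth)
    predicted = sorted(predicted, key=lambda j: j.key)
    per_class = {c: ClassStats() for c in _CLASSES}
    for t in truth:
        per_class.setdefault(t[2], ClassStats()).n_truth += 1
    for p in predicted:
        per_class.setdefault(p.cls, ClassStats()).n_predicted += 1

    pairs = []
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth):
            d = _compatible(p, t, tolerance)
            if d is not None:
                pairs.append((d, pi, ti))
    pairs.sort()
    used_p, used_t = set(), set()
    n_correct = 0
    for d, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        n_correct += 1
        per_class[truth[ti][2]].n_correct += 1

    n_truth = len(truth)
    n_predicted = len(predicted)
    n_wrong = n_predicted - n_correct
    recall = None if n_truth == 0 else n_correct / n_truth
    fpr = None if n_predicted == 0 else n_wrong / n_predicted
    precision = None if fpr is None else 1 - fpr
    return EvalReport(
        n_truth=n_truth,
        n_predicted=n_predicted,
        n_correct=n_correct,
        n_wrong=n_wrong,
        recall=recall,
        fpr=fpr,
        precision=precision,
        per_class=per_class,
    )


def truth_from_frame(df: pd.DataFrame) -> List[TruthEntry]:
    """Truth entries from a junction catalog (or per-read truth) table."""
    cols = [
        "donor_chrom", "donor_pos", "donor_strand",
        "acceptor_chrom", "acceptor_pos", "acceptor_strand", "class",
    ]
    seen = df[cols].drop_duplicates()
    out: List[TruthEntry] = []
    for row in seen.itertuples(index=False, name=None):
        out.append(
            (
                (row[0], int(row[1]), row[2]),
                (row[3], int(row[4]), row[5]),
                row[6],
            )
        )
    return out
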