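"""Recovery metrics against planted ground truth."""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .diffexpr import significant_records
from .network import CeRNATriad
from .simulate import GroundTruth


class DERecovery(NamedTuple):
    sensitivity: float       # planted features recalled with correct direction
    fdp: float               # false-discovery proportion among calls
    n_called: int
    n_planted: int


def de_recovery(de_records: pd.DataFrame,
                planted: Mapping[str, str]) -> DERecovery:
    """Sensitivity and empirical FDP of one differential screen.

    A planted feature counts as recovered when it is called significant
    with the planted direction; any significant call outside the
    planted set is a false discovery.
    """
    sig = significant_records(de_records)
    called = dict(zip(sig.index, sig["regulation"]))
    hits = sum(1 for fid, d in planted.items() if called.get(fid) == d)
    false = sum(1 for fid in called if fid not in planted)
    sensitivity = hits / len(planted) if planted else float("nan")
    fdp = false / len(called) if called else 0.0
    return DERecovery(sensitivity, fdp, len(called), len(planted))


class TriadRecovery(NamedTuple):
    recovered: float         # fraction of planted triads emitted
    n_planted: int
    n_emitted: int
    inconsistent: int        # emitted triads violating the sponge rule


def triad_recovery(triads: Sequence[CeRNATriad],
                   truth: GroundTruth) -> TriadRecovery:
    emitted = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triads}
    planted = set(truth.planted_triads)
    hits = len(planted & emitted)
    inconsistent = sum(
        1 for t in triads
        if t.mirna_direction == t.mrna_direction
        or t.mirna_direction == t.lncrna_direction)
    recovered = hits / len(planted) if planted else float("nan")
    return TriadRecovery(recovered, len(planted), len(emitted), inconsistent)
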