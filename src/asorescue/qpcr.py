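"""Relative qPCR quantification (efficiency-scaled ddCt).

Each sample's target quantity is normalised to the geometric mean of the
reference-gene quantities measured in the same sample,

    NQ_s = E^(-Ct_target,s) / geomean_r E^(-Ct_r,s)
         = E^(mean_r Ct_r,s - Ct_target,s),

with amplification efficiency E = 2 by default (perfect doubling per
cycle). Technical replicates are averaged on the Ct scale first. Expression
is then reported relative to the control group: percent_s = 100 * NQ_s /
mean(NQ over control samples), so the control-group mean is exactly 100.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import CtTable

logger = logging.getLogger("asorescue")

REPLICATE_SPREAD_WARN = 0.5  # cycles


class QpcrError(ValueError):
    pass


def normalised_quantity(
    ct_table: CtTable,
    target: str,
    refs: list[str] | None = None,
    *,
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-sample normalised quantity of ``target`` against reference genes."""
    if efficiency <= 1:
        raise QpcrError(f"amplification efficiency must be > 1, got {efficiency}")
    d = ct_table.data
    refs = list(refs) if refs is not None else ct_table.reference_assays
    if not refs:
        raise QpcrError("no reference assays")
    mean_ct = d.groupby(["sample", "assay"])["ct"].mean()
    spread = d.groupby(["sample", "assay"])["ct"].agg(lambda x: x.max() - x.min())
    wide = spread[spread > REPLICATE_SPREAD_WARN]
    for (sample, assay), s in wide.items():
        logger.warning("replicate Ct spread %.2f cycles for %s / %s",
                       s, sample, assay)
    samples = sorted(d["sample"].unique())
    out = {}
    for s in samples:
        if (s, target) not in mean_ct.index:
            raise QpcrError(f"sample {s!r} lacks target assay {target!r}")
        for r in refs:
            if (s, r) not in mean_ct.index:
                raise QpcrError(f"sample {s!r} lacks reference assay {r!r}")
        ref_mean = np.mean([mean_ct[(s, r)] for r in refs])
        out[s] = efficiency ** (ref_mean - mean_ct[(s, target)])
    return pd.Series(out, name="NQ")


def relative_to_control(nq: pd.Series, groups) -> pd.DataFrame:
    """Percent-of-control expression; control-group mean is exactly 100.

    ``groups`` maps sample -> 'control' / 'proband'.
    """
    groups = dict(groups)
    controls = [s for s in nq.index if groups.get(s) == "control"]
    if not controls:
        raise QpcrError("no control samples in comparison")
    ctrl_mean = float(nq[controls].mean())
    if not np.isfinite(ctrl_mean) or ctrl_mean <= 0:
        raise QpcrError(f"control mean quantity is {ctrl_mean}; cannot normalise")
    out = pd.DataFrame(
        {
            "NQ": nq,
            "group": [groups[s] for s in nq.index],
            "percent_of_control": 100.0 * nq / ctrl_mean,
        }
    )
    out.index.name = "sample"
    return out


def relative_expression(
    ct_table: CtTable,
    target: str,
    refs: list[str] | None = None,
    *,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Convenience composition: normalised quantity then percent-of-control."""
    nq = normalised_quantity(ct_table, target, refs, efficiency=efficiency)
    return relative_to_control(nq, ct_table.groups)
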