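"""Power / false-discovery evaluation of ranked GWAS results.

Given the list of markers ranked by ascending p-value and the simulation
truth, at each rank cut t:

    power(t) = (# true QTNs among the top t) / m_r
    fdr(t)   = (# non-QTN markers among the top t) / M_f

with m_r the number of simulated QTNs and M_f the number of non-QTN
markers. As defined, fdr is a false-positive *rate* over all non-causal
markers (it divides by M_f, not by t); the conventional false-discovery
proportion FP/t is available behind ``conventional=True``. Both curves end
at 1 when the full list is declared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimTruth


@dataclass
class PowerFDRCurve:
    rank_cut: np.ndarray
    power: np.ndarray
    fdr: np.ndarray
    m_r: int
    M_f: int
    power_sd: np.ndarray | None = None
    fdr_sd: np.ndarray | None = None


def match_qtn(
    ranked: pd.DataFrame,
    truth: SimTruth,
    marker_map: pd.DataFrame,
    window_bp: int = 0,
    dedup: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Flag each ranked marker as true QTN or not, deduplicating GbyE copies.

    ``ranked`` must carry a ``marker_id`` column sorted by ascending p.
    With ``dedup`` (default) each original marker enters the list once (its
    best-ranked copy); each QTN is creditable once — later markers hitting
    an already-credited QTN are dropped from the list (neither TP nor FP).
    ``window_bp`` > 0 credits markers within that distance of a QTN on the
    same chromosome.
    """
    known = set(marker_map["id"])
    for mid in ranked["marker_id"]:
        if mid not in known:
            raise ValueError(f"ranked marker {mid!r} not in marker map")
    qtn_ids = set(marker_map["id"].iloc[truth.qtn_indices])
    if dedup:
        ranked = ranked.drop_duplicates(subset="marker_id", keep="first")
    if window_bp == 0:
        flags = ranked["marker_id"].isin(qtn_ids).to_numpy()
        return ranked.reset_index(drop=True), flags
    mm = marker_map.set_index("id")
    qtn_pos = mm.loc[sorted(qtn_ids)][["chrom", "pos"]]
    credited: set[str] = set()
    flags_l, keep_l = [], []
    for mid in ranked["marker_id"]:
        chrom, pos = mm.loc[mid, "chrom"], mm.loc[mid, "pos"]
        near = qtn_pos[
            (qtn_pos["chrom"] == chrom) & (abs(qtn_pos["pos"] - pos) <= window_bp)
        ]
        if len(near) == 0:
            flags_l.append(False)
            keep_l.append(True)
            continue
        fresh = [q for q in near.index if q not in credited]
        if fresh:
            credited.add(fresh[0])
            flags_l.append(True)
            keep_l.append(True)
        else:
            flags_l.append(False)
            keep_l.append(False)  # QTN already credited: neither TP nor FP
    keep = np.asarray(keep_l)
    return ranked.loc[keep].reset_index(drop=True), np.asarray(flags_l)[keep]


def power_fdr_curve(
    flags: np.ndarray,
    m_r: int,
    M_f: int | None = None,
    conventional: bool = False,
) -> PowerFDRCurve:
    """Cumulative power and false-positive-rate curve over rank cuts.

    ``flags`` is the true/false QTN status of the deduplicated ranked list
    (ascending p). ``M_f`` defaults to the number of False flags. With
    ``M_f = 0`` the fdr curve is identically 0.
    """
    flags = np.asarray(flags, dtype=bool)
    T = len(flags)
    if m_r <= 0:
        raise ValueError("m_r must be positive")
    if M_f is None:
        M_f = int((~flags).sum())
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    power = tp / m_r
    if conventional:
        fdr = fp / np.arange(1, T + 1)
    else:
        fdr = fp / M_f if M_f > 0 else np.zeros(T)
    return PowerFDRCurve(np.arange(1, T + 1), power, fdr, m_r, int(M_f))


def curve_from_results(
    results: pd.DataFrame,
    truth: SimTruth,
    marker_map: pd.DataFrame,
    window_bp: int = 0,
    conventional: bool = False,
) -> PowerFDRCurve:
    """Rank a scan table by p (ties: chrom, pos) and build the curve."""
    mm = marker_map.rename(columns={"id": "marker_id"})
    merged = results.merge(mm, on="marker_id", how="left")
    merged = merged.sort_values(
        ["p", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    ranked, flags = match_qtn(merged, truth, marker_map, window_bp=window_bp)
    m_r = truth.nqtn
    M_f = len(marker_map) - m_r
    return power_fdr_curve(flags, m_r, M_f, conventional=conventional)


def average_curves(curves: list[PowerFDRCurve]) -> PowerFDRCurve:
    """Pointwise mean and sample-SD band over replicate curves."""
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if (c.m_r, c.M_f, len(c.power)) != (ref.m_r, ref.M_f, len(ref.power)):
            raise ValueError("curves come from heterogeneous designs")
    P = np.vstack([c.power for c in curves])
    F = np.vstack([c.fdr for c in curves])
    ddof = 1 if len(curves) > 1 else 0
    return PowerFDRCurve(
        ref.rank_cut, P.mean(axis=0), F.mean(axis=0), ref.m_r, ref.M_f,
        power_sd=P.std(axis=0, ddof=ddof), fdr_sd=F.std(axis=0, ddof=ddof),
    )


def power_at_fdr(curve: PowerFDRCurve, fdr_level: float) -> float:
    """Maximum power among rank cuts with fdr <= fdr_level (0 if none)."""
    ok = curve.fdr <= fdr_level
    return float(curve.power[ok].max()) if ok.any() else 0.0


def write_curve(curve: PowerFDRCurve, path, sep: str = "\t"):
    df = pd.DataFrame({"rank": curve.rank_cut, "power": curve.power, "fdr": curve.fdr})
    if curve.power_sd is not None:
        df["power_sd"] = curve.power_sd
        df["fdr_sd"] = curve.fdr_sd
    df.to_csv(path, sep=sep, index=False)


def plot_power_fdr(curves: dict[str, PowerFDRCurve], path=None, title: str = ""):
    """Power-vs-FDR comparison figure (one line per labeled method)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.plot(c.fdr, c.power, label=label)
    ax.set_xlabel("FDR")
    ax.set_ylabel("Power")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
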