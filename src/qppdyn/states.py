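"""Per-timepoint brain states from component magnitudes, and their summaries.

A "brain state" here is deliberately simple: at each timepoint the state is
the index of the component with the largest score magnitude.  States feed
three summaries: incidence tables (fraction of scan time each state
dominates, per subject and/or condition), carpet matrices (label rasters
sorted across time or subjects), and first/last segment magnitude summaries
used to detect slow drift across a scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cpca import StateMagnitudes

__all__ = [
    "OTHER_STATE",
    "StateSequence",
    "assign_dominant_state",
    "incidence",
    "incidence_table",
    "carpet_matrix",
    "plot_carpet",
    "segment_magnitude_summary",
    "paired_segment_differences",
    "condition_summary",
]

#: integer label used for "a non-retained component won" (printed as "other")
OTHER_STATE = 0

#: sentinel padding value for ragged carpet rows
CARPET_PAD = -1


@dataclass
class StateSequence:
    """Per-timepoint dominant-pattern labels.

    Labels are 1..k_retain, or ``OTHER_STATE`` (0) when the dominance pool
    is "all" and a non-retained component wins.
    """

    labels: np.ndarray
    magnitudes: np.ndarray
    k_retain: int
    dominance_pool: str  # "retained" or "all"

    def __len__(self) -> int:
        return len(self.labels)


def assign_dominant_state(
    magnitudes: StateMagnitudes | np.ndarray,
    k_retain: int,
    dominance_pool: str = "retained",
) -> StateSequence:
    """Label each timepoint with its strongest component.

    ``dominance_pool="retained"`` competes only the first ``k_retain``
    components; ``"all"`` competes every extracted component and labels
    timepoints won by a non-retained component as "other".  Ties break
    toward the lower component index.
    """
    mags = magnitudes.magnitudes if isinstance(magnitudes, StateMagnitudes) else np.asarray(magnitudes)
    if mags.ndim != 2 or mags.size == 0:
        raise ValueError("magnitudes must be a nonempty timepoints x K matrix")
    K = mags.shape[1]
    if not (1 <= k_retain <= K):
        raise ValueError(f"k_retain must be in [1, {K}]")
    if dominance_pool not in ("retained", "all"):
        raise ValueError("dominance_pool must be 'retained' or 'all'")
    pool = mags[:, :k_retain] if dominance_pool == "retained" else mags
    winner = np.argmax(pool, axis=1)  # argmax breaks ties toward lower index
    labels = winner + 1
    if dominance_pool == "all":
        labels = np.where(winner < k_retain, labels, OTHER_STATE)
    return StateSequence(
        labels=labels, magnitudes=mags, k_retain=k_retain, dominance_pool=dominance_pool
    )


def _state_columns(k_retain: int, include_other: bool) -> list:
    cols: list = list(range(1, k_retain + 1))
    if include_other:
        cols.append("other")
    return cols


def incidence(seq: StateSequence, include_other: bool = False) -> pd.Series:
    """Fraction of timepoints spent in each state.

    With the "all" dominance pool and ``include_other=False`` the fractions
    can sum below 1: timepoints won by non-retained components are counted
    in the denominator but reported under no retained state.
    """
    if len(seq) == 0:
        raise ValueError("empty state sequence")
    n = len(seq)
    cols = _state_columns(seq.k_retain, include_other)
    vals = [(seq.labels == s).sum() / n for s in range(1, seq.k_retain + 1)]
    if include_other:
        vals.append((seq.labels == OTHER_STATE).sum() / n)
    return pd.Series(vals, index=cols, name="incidence")


def incidence_table(
    sequences: Mapping, include_other: bool = False
) -> pd.DataFrame:
    """Incidence rows per subject (or subject x condition) identifier.

    ``sequences`` maps an identifier (a string or tuple) to a
    ``StateSequence``; rows with tuple keys get a MultiIndex.
    """
    rows = {key: incidence(seq, include_other) for key, seq in sequences.items()}
    table = pd.DataFrame(rows).T
    table.index.name = "subject"
    return table


def carpet_matrix(
    state_sequences: Sequence[StateSequence],
    sort_mode: str = "none",
) -> tuple[np.ndarray, dict]:
    """Stack state sequences into a label raster (rows = sequences).

    ``by_time`` sorts the labels within each timepoint column (requires
    equal lengths; "other" sorts after the retained states); ``by_subject``
    orders rows by state-1 incidence, descending; ``none`` keeps input
    order.  Ragged inputs are padded with ``CARPET_PAD``.  Returns the
    matrix and ordering metadata.
    """
    if len(state_sequences) == 0:
        raise ValueError("need at least one state sequence")
    lengths = [len(s) for s in state_sequences]
    k = state_sequences[0].k_retain
    if sort_mode == "by_time":
        if len(set(lengths)) > 1:
            raise ValueError(
                f"by_time sorting requires equal-length sequences, got lengths {sorted(set(lengths))}"
            )
        M = np.stack([s.labels for s in state_sequences])
        # sort each column by state label, with "other" (0) placed last
        key = np.where(M == OTHER_STATE, k + 1, M)
        order = np.argsort(key, axis=0, kind="stable")
        out = np.take_along_axis(M, order, axis=0)
        return out, {"sort_mode": sort_mode, "row_order": None}
    T = max(lengths)
    M = np.full((len(state_sequences), T), CARPET_PAD, dtype=int)
    for i, s in enumerate(state_sequences):
        M[i, : len(s)] = s.labels
    if sort_mode == "none":
        return M, {"sort_mode": sort_mode, "row_order": list(range(len(state_sequences)))}
    if sort_mode == "by_subject":
        inc1 = np.array([(s.labels == 1).mean() for s in state_sequences])
        order = np.argsort(-inc1, kind="stable")
        return M[order], {"sort_mode": sort_mode, "row_order": order.tolist()}
    raise ValueError(f"unknown sort mode {sort_mode!r}")


def plot_carpet(matrix: np.ndarray, path, k_retain: int | None = None) -> None:
    """Render a carpet matrix (rows = sequences, columns = timepoints) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = int(matrix.max()) if k_retain is None else k_retain
    fig, ax = plt.subplots(figsize=(8, 0.3 * max(matrix.shape[0], 4) + 1))
    im = ax.imshow(
        np.ma.masked_where(matrix == CARPET_PAD, matrix),
        aspect="auto", interpolation="nearest", cmap="viridis", vmin=0, vmax=k,
    )
    ax.set_xlabel("timepoint")
    ax.set_ylabel("sequence")
    fig.colorbar(im, ax=ax, label="state")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def segment_magnitude_summary(
    magnitudes_per_subject: Mapping[str, np.ndarray],
    first_n: int,
    last_n: int,
) -> pd.DataFrame:
    """Mean and SD of each component's magnitude in the first/last segments.

    Long-format rows: subject, component (1-based), segment ("first" or
    "last"), mean, sd.  Segments must not overlap.
    """
    rows = []
    for sub, mags in magnitudes_per_subject.items():
        mags = np.asarray(mags)
        T, K = mags.shape
        if first_n + last_n > T:
            raise ValueError(
                f"subject {sub!r}: segments overlap (first_n + last_n = "
                f"{first_n + last_n} > {T} timepoints)"
            )
        for seg, chunk in (("first", mags[:first_n]), ("last", mags[T - last_n :])):
            for k in range(K):
                rows.append(
                    {
                        "subject": sub,
                        "component": k + 1,
                        "segment": seg,
                        "mean": chunk[:, k].mean(),
                        "sd": chunk[:, k].std(ddof=1),
                    }
                )
    return pd.DataFrame(rows)


def paired_segment_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """Last-minus-first mean-magnitude difference per subject x component."""
    wide = summary.pivot_table(
        index=["subject", "component"], columns="segment", values="mean"
    )
    wide["difference"] = wide["last"] - wide["first"]
    return wide.reset_index()


def condition_summary(
    state_sequences: Mapping[tuple, "StateSequence"],
    magnitudes: Mapping[tuple, np.ndarray],
) -> pd.DataFrame:
    """Per subject x condition x component incidence and mean magnitude.

    Keys are ``(subject_id, condition_id)`` tuples; every subject must have
    every condition (repeated-measures designs need complete cells).
    """
    if set(state_sequences) != set(magnitudes):
        raise ValueError("state sequences and magnitudes must share keys")
    subjects = sorted({k[0] for k in state_sequences})
    conditions = sorted({k[1] for k in state_sequences})
    missing = [
        (s, c) for s in subjects for c in conditions if (s, c) not in state_sequences
    ]
    if missing:
        raise ValueError(f"missing subject/condition cells: {missing}")
    rows = []
    for (sub, cond), seq in state_sequences.items():
        if len(seq) < 1:
            raise ValueError(f"empty sequence for {(sub, cond)}")
        inc = incidence(seq, include_other=False)
        mags = np.asarray(magnitudes[(sub, cond)])
        for k in range(1, seq.k_retain + 1):
            rows.append(
                {
                    "subject": sub,
                    "condition": cond,
                    "component": k,
                    "incidence": inc[k],
                    "mean_magnitude": mags[:, k - 1].mean(),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["subject", "condition", "component"]).reset_index(drop=True)
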