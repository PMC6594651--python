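"""Binding-site attribution from pooled convolution positions.

The globally max-pooled convolution results of a trained model mark, per
filter, the window of residues that most strongly matches its learned local
pattern. If the model has learned patterns relevant to binding, those argmax
windows should cover annotated ligand-binding residues more often than chance.

The test: for each window size, the observed statistic counts how the argmax
windows of all filters of that size cover the annotated residues — either as
(window, residue) covering events (default; it has a closed-form null
expectation) or as the number of distinct residues covered. A Monte-Carlo
null places the same number of windows uniformly at random over the valid
start positions, ``n_reps`` times (default 10,000 replicates of
``n_results`` = 128 windows), and a normal distribution is fitted to the
replicate statistics. The observed count is scored by the fitted normal's
upper tail (right-tailed test; with 10,000 replicates the t correction is
negligible). P-values are Benjamini-Hochberg adjusted across window sizes
within each entry — since we do not know in advance which window size
detects the site — and the entry is summarised by its minimum adjusted
p-value, thresholded at the 1%, 5% and 10% significance levels.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .encoding import EncodedProtein
from .io_data import BindingSiteAnnotation
from .nn.model import DTIModel, ModelState

DEFAULT_N_RESULTS = 128
DEFAULT_N_REPS = 10_000
DEFAULT_LEVELS = (0.01, 0.05, 0.10)


@dataclass(frozen=True)
class NullDistribution:
    """Fitted normal null for one (entry geometry, window size)."""

    window_size: int
    n_results: int
    n_reps: int
    mean: float
    sd: float
    mode: str = "events"

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates to fit a null")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class AttributionResult:
    """Per-entry attribution outcome across window sizes."""

    entry_id: str
    protein_id: str
    window_sizes: tuple[int, ...]
    observed: dict[int, int]
    p_values: dict[int, float]
    p_adjusted: dict[int, float]
    nulls: dict[int, NullDistribution]
    min_adjusted_p: float
    significant: dict[float, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.significant:
            self.significant = {q: self.min_adjusted_p < q for q in DEFAULT_LEVELS}


def window_coverage(
    starts: Iterable[int],
    window_size: int,
    residues: Iterable[int],
    mode: str = "events",
) -> int:
    """Count how windows starting at ``starts`` cover the annotated residues.

    A window at 1-based start j covers residues j .. j+window_size-1
    inclusive. ``mode="events"`` (default) counts (window, residue) covering
    pairs, so duplicated starts count multiply; ``mode="residues"`` counts
    distinct residues covered by at least one window.
    """
    residues = set(residues)
    if not residues:
        raise ValueError("empty residue set")
    if mode not in ("events", "residues"):
        raise ValueError(f"unknown mode {mode!r}")
    starts = list(starts)
    if any(s < 1 for s in starts):
        raise ValueError("window starts are 1-based")
    if mode == "events":
        return sum(
            1 for s in starts for r in residues if s <= r <= s + window_size - 1
        )
    covered = set()
    for s in starts:
        covered.update(r for r in residues if s <= r <= s + window_size - 1)
    return len(covered)


def expected_events_coverage(
    true_length: int, window_size: int, n_results: int, residues: Iterable[int]
) -> float:
    """Closed-form null mean of the events statistic under uniform placement:
    n_results * sum_r (#starts covering r) / (#valid starts)."""
    n_valid = true_length - window_size + 1
    if n_valid < 1:
        raise ValueError("window longer than sequence")
    total = 0
    for r in residues:
        lo = max(1, r - window_size + 1)
        hi = min(r, n_valid)
        total += max(0, hi - lo + 1)
    return n_results * total / n_valid


def sample_null(
    true_length: int,
    window_size: int,
    n_results: int = DEFAULT_N_RESULTS,
    n_reps: int = DEFAULT_N_REPS,
    residues: Iterable[int] = (),
    mode: str = "events",
    seed: int = 0,
) -> NullDistribution:
    """Monte-Carlo null of the coverage statistic under uniform placement.

    Each replicate draws ``n_results`` window starts uniformly with
    replacement from the valid positions {1 .. true_length-window_size+1},
    computes the coverage of ``residues``, and the replicates' sample mean
    and standard deviation define the fitted normal null.
    """
    residues = sorted(set(residues))
    if not residues:
        raise ValueError("empty residue set")
    if residues[-1] > true_length:
        raise ValueError(
            f"residue index {residues[-1]} exceeds sequence length {true_length}"
        )
    n_valid = true_length - window_size + 1
    if n_valid < 1:
        raise ValueError(
            f"window size {window_size} exceeds sequence length {true_length}"
        )
    if n_results < 1 or n_reps < 2:
        raise ValueError("need n_results >= 1 and n_reps >= 2")
    rng = np.random.default_rng(seed)
    res_ind = np.zeros(true_length + 1, dtype=np.int64)
    res_ind[residues] = 1
    prefix = np.cumsum(res_ind)
    # residues covered by a window starting at s (1-based)
    starts_axis = np.arange(1, n_valid + 1)
    cov_per_start = prefix[np.minimum(starts_axis + window_size - 1, true_length)] - \
        prefix[starts_axis - 1]
    if mode == "events":
        draws = rng.integers(0, n_valid, size=(n_reps, n_results))
        stats_vec = cov_per_start[draws].sum(axis=1)
    elif mode == "residues":
        res_arr = np.array(residues)
        lo = np.maximum(1, res_arr - window_size + 1)
        hi = np.minimum(res_arr, n_valid)
        stats_list = []
        chunk = max(1, int(2e6 // max(n_valid, 1)))
        for i in range(0, n_reps, chunk):
            m = min(chunk, n_reps - i)
            presence = np.zeros((m, n_valid), dtype=np.int32)
            rows = np.repeat(np.arange(m), n_results)
            cols = rng.integers(0, n_valid, size=(m, n_results)).ravel()
            presence[rows, cols] = 1
            cum = np.concatenate([np.zeros((m, 1), dtype=np.int32),
                                  np.cumsum(presence, axis=1)], axis=1)
            hit = cum[:, hi] - cum[:, lo - 1] > 0  # any start in [lo, hi]
            valid_res = hi >= lo
            stats_list.append((hit & valid_res).sum(axis=1))
        stats_vec = np.concatenate(stats_list)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NullDistribution(
        window_size=window_size,
        n_results=n_results,
        n_reps=n_reps,
        mean=float(stats_vec.mean()),
        sd=float(stats_vec.std(ddof=1)),
        mode=mode,
    )


def right_tailed_p(observed: float, null: NullDistribution) -> float:
    """Upper-tail probability of the fitted normal at the observed count.

    Degenerate nulls (sd = 0) give p = 1 below the mean, p = 0.5 at the mean
    (matching the symmetry of the continuous case) and p = 0 above it, with
    a warning.
    """
    if null.sd == 0:
        warnings.warn("degenerate null (sd = 0); p-value is a point test",
                      stacklevel=2)
        if observed == null.mean:
            return 0.5
        return 1.0 if observed < null.mean else 0.0
    return float(stats.norm.sf(observed, loc=null.mean, scale=null.sd))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_model(state_or_model: DTIModel | ModelState) -> DTIModel:
    if isinstance(state_or_model, DTIModel):
        return state_or_model
    return DTIModel.from_state(state_or_model)


def attribute_entry(
    state: DTIModel | ModelState,
    protein: EncodedProtein,
    annotation: BindingSiteAnnotation,
    n_reps: int = DEFAULT_N_REPS,
    mode: str = "events",
    seed: int = 0,
    *,
    unique_starts: bool = False,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> AttributionResult:
    """Test one binding-site annotation against the model's argmax windows.

    For every window size the observed statistic is the coverage of the
    annotated residues by the argmax windows of all filters of that size
    (duplicate argmax positions count multiply unless ``unique_starts``);
    each window size gets its own Monte-Carlo null and right-tailed p-value,
    BH adjustment runs across window sizes within the entry, and the minimum
    adjusted p-value summarises the entry.
    """
    model = _as_model(state)
    residues = set(annotation.residues)
    if max(residues) > protein.true_length:
        raise ValueError(
            f"entry {annotation.entry_id!r}: residue {max(residues)} beyond "
            f"protein length {protein.true_length}"
        )
    trace = model.protein_conv_trace(protein)
    observed: dict[int, int] = {}
    nulls: dict[int, NullDistribution] = {}
    p_values: dict[int, float] = {}
    used_windows: list[int] = []
    rng = np.random.default_rng([seed, protein.true_length])
    for ws, (_pooled, argmax) in trace.items():
        starts = [int(s) for s in argmax if s >= 1]
        if not starts:  # window longer than the sequence: no valid placement
            continue
        if unique_starts:
            starts = sorted(set(starts))
        obs = window_coverage(starts, ws, residues, mode)
        null = sample_null(protein.true_length, ws, len(starts), n_reps,
                           residues, mode, seed=int(rng.integers(2 ** 31)))
        observed[ws] = obs
        nulls[ws] = null
        p_values[ws] = right_tailed_p(obs, null)
        used_windows.append(ws)
    if not used_windows:
        raise ValueError(
            f"entry {annotation.entry_id!r}: no window size fits the sequence"
        )
    adjusted = bh_adjust([p_values[ws] for ws in used_windows])
    p_adjusted = {ws: float(a) for ws, a in zip(used_windows, adjusted)}
    min_adj = min(p_adjusted.values())
    return AttributionResult(
        entry_id=annotation.entry_id,
        protein_id=annotation.protein_id,
        window_sizes=tuple(used_windows),
        observed=observed,
        p_values=p_values,
        p_adjusted=p_adjusted,
        nulls=nulls,
        min_adjusted_p=min_adj,
        significant={q: min_adj < q for q in levels},
    )


def summarize_significance(
    results: Sequence[AttributionResult],
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> dict[float, float]:
    """Fraction of entries whose minimum adjusted p-value falls below each
    significance level; monotone non-decreasing in the level."""
    if not results:
        raise ValueError("no attribution results to summarise")
    return {
        q: sum(r.min_adjusted_p < q for r in results) / len(results)
        for q in levels
    }


def top_k_coverage(
    state: DTIModel | ModelState, protein: EncodedProtein, k: int = 5
) -> dict[int, int]:
    """Residue -> covering-window count over the top-k filters per window.

    For each window size the k filters with the largest pooled values are
    selected and each residue is counted once per selected window covering
    it — the simplified view used to render residue highlights.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = _as_model(state)
    if k > model.config.filters_per_window:
        warnings.warn(
            f"k={k} exceeds the filter count "
            f"{model.config.filters_per_window}; using all filters",
            stacklevel=2,
        )
        k = model.config.filters_per_window
    counts: dict[int, int] = {}
    for ws, (pooled, argmax) in model.protein_conv_trace(protein).items():
        valid = argmax >= 1
        if not valid.any():
            continue
        order = np.argsort(-pooled[valid], kind="stable")[:k]
        for s in np.asarray(argmax)[valid][order]:
            for r in range(int(s), min(int(s) + ws, protein.true_length + 1)):
                counts[r] = counts.get(r, 0) + 1
    return counts


def write_attribution_csv(
    results: Sequence[AttributionResult], path: str | Path
) -> None:
    """One row per (entry, window size): observed count, p, adjusted p, and
    the per-entry minimum adjusted p repeated for convenience."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["entry_id", "protein_id", "window_size", "observed",
                    "null_mean", "null_sd", "n_results", "n_reps",
                    "p_value", "p_adjusted", "min_adjusted_p"])
        for r in results:
            for ws in r.window_sizes:
                null = r.nulls[ws]
                w.writerow([r.entry_id, r.protein_id, ws, r.observed[ws],
                            f"{null.mean:.6g}", f"{null.sd:.6g}",
                            null.n_results, null.n_reps,
                            f"{r.p_values[ws]:.6g}", f"{r.p_adjusted[ws]:.6g}",
                            f"{r.min_adjusted_p:.6g}"])
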