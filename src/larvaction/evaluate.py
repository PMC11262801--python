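"""Screen-style evaluation of behavioural readouts.

Implements the stimulus-aligned analysis used in large inactivation screens:
per-action probability time series, larva counts in a short post-onset
analysis window (by convention 1 s after a 45-s onset), Pearson chi-square
tests of each test line against a control line with Bonferroni correction
over a configurable number of comparisons, three-level outcomes (positive
difference, negative difference, absence of effect), inter-tagger outcome
agreement, and macro-f1 scoring of per-timestep labels.

Counting is larva-level by default: a larva "performs the action in the
window" if any of its timesteps in the window carries that label. The
chi-square variant is Pearson without Yates continuity correction (the
continuity-corrected variant is switchable). The significance level defaults
to 0.05; the Bonferroni multiplier defaults to the number of tests actually
performed and can be pinned to an external comparison inventory (e.g. 471).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score

from .tagger import ActionDictionary
from .trackdata_io import LabelSet, Track

__all__ = [
    "ComparisonResult",
    "AgreementSummary",
    "probability_timeseries",
    "window_counts",
    "chi2_compare",
    "screen_compare",
    "agreement",
    "macro_f1",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One line-versus-control comparison for one action."""

    line: str
    action: str
    k_test: int
    n_test: int
    k_control: int
    n_control: int
    chi2: float
    p_raw: float
    p_corrected: float
    outcome: str  # positive | negative | none | untestable


@dataclass(frozen=True)
class AgreementSummary:
    """Concordance between two sets of three-level outcomes."""

    concordant: int
    effect_lost: int
    effect_gained: int
    opposite: int

    @property
    def total(self) -> int:
        return self.concordant + self.effect_lost + self.effect_gained + self.opposite

    @property
    def concordance(self) -> float:
        return self.concordant / self.total if self.total else float("nan")


def _times_for(labels: LabelSet, tracks: list[Track] | None, larva_id: int) -> np.ndarray | None:
    if larva_id in labels.times:
        return labels.times[larva_id]
    if tracks is not None:
        for track in tracks:
            if track.larva_id == larva_id:
                return track.t
    return None


def probability_timeseries(
    labels: LabelSet,
    tracks: list[Track] | None,
    dictionary: ActionDictionary,
    bin_seconds: float = 1.0,
) -> pd.DataFrame:
    """Per-action population probabilities over time bins.

    For each bin, probability = (larvae carrying the action label at any
    timestep in the bin) / (larvae tracked in the bin). Untagged timesteps
    reduce the numerator only. Bins with no tracked larva are omitted.
    Returns a tidy frame (action, t_bin, probability, n).
    """
    spans = []
    for larva_id in labels.assignments:
        t = _times_for(labels, tracks, larva_id)
        if t is not None and len(t):
            spans.append((t[0], t[-1]))
    if not spans:
        return pd.DataFrame(columns=["action", "t_bin", "probability", "n"])
    t0 = min(s for s, _ in spans)
    t1 = max(e for _, e in spans)
    edges = np.arange(t0, t1 + bin_seconds, bin_seconds)

    name_of = labels.names
    rows = []
    for lo in edges:
        hi = lo + bin_seconds
        tracked = 0
        performing = {name: 0 for name in dictionary.names}
        for larva_id, vec in labels.assignments.items():
            t = _times_for(labels, tracks, larva_id)
            if t is None:
                continue
            inside = (t >= lo) & (t < hi)
            if not inside.any():
                continue
            tracked += 1
            seen = set()
            for step in np.nonzero(inside)[0]:
                for idx in vec[step]:
                    seen.add(name_of[idx])
            for name in seen:
                if name in performing:
                    performing[name] += 1
        if tracked == 0:
            continue
        for name in dictionary.names:
            rows.append({"action": name, "t_bin": float(lo),
                         "probability": performing[name] / tracked, "n": tracked})
    return pd.DataFrame(rows, columns=["action", "t_bin", "probability", "n"])


def window_counts(
    labels: LabelSet,
    tracks: list[Track] | None,
    action: str,
    window: tuple[float, float],
) -> tuple[int, int]:
    """Larva-level counts in [t0, t1): ``n`` larvae with at least one tagged
    timestep in the window, ``k`` of them carrying ``action`` there."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    try:
        action_idx = labels.label_index(action)
    except ValueError:
        action_idx = None
    k = n = 0
    for larva_id, vec in labels.assignments.items():
        t = _times_for(labels, tracks, larva_id)
        if t is None:
            continue
        inside = np.nonzero((t >= t0) & (t < t1))[0]
        tagged = [step for step in inside if vec[step]]
        if not tagged:
            continue
        n += 1
        if action_idx is not None and any(action_idx in vec[step] for step in tagged):
            k += 1
    return k, n


def chi2_compare(
    test: tuple[int, int],
    control: tuple[int, int],
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[k_t, n_t-k_t], [k_c, n_c-k_c]],
    1 degree of freedom. Degenerate tables (a zero margin) give (0, 1)."""
    k_t, n_t = test
    k_c, n_c = control
    if not (0 <= k_t <= n_t and 0 <= k_c <= n_c):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if n_t == 0 or n_c == 0:
        raise ValueError("n must be > 0 in both groups")
    a, b = k_t, n_t - k_t
    c, d = k_c, n_c - k_c
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    total = n_t + n_c
    delta = abs(a * d - b * c)
    if continuity_correction:
        delta = max(delta - total / 2.0, 0.0)
    chi2 = total * delta**2 / (n_t * n_c * col1 * col2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def screen_compare(
    lines: dict[str, tuple[LabelSet, list[Track] | None]],
    control_name: str,
    dictionary: ActionDictionary,
    window: tuple[float, float],
    m: int | None = None,
    alpha: float = 0.05,
    continuity_correction: bool = False,
) -> list[ComparisonResult]:
    """Compare every non-control line against the control, per action.

    ``m`` is the Bonferroni multiplier; it defaults to the number of tests
    actually performed, and can be pinned to an external inventory size.
    Outcome is ``positive`` when corrected p < alpha and the test-line
    proportion exceeds control, ``negative`` for the reverse, ``none``
    otherwise; lines with no countable larva in the window are ``untestable``.
    """
    if control_name not in lines:
        raise ValueError(f"control line {control_name!r} not among lines")
    control_labels, control_tracks = lines[control_name]
    test_names = [name for name in lines if name != control_name]
    n_tests = len(test_names) * len(dictionary.names)
    multiplier = m if m is not None else n_tests
    if multiplier < n_tests:
        raise ValueError(f"m={multiplier} is smaller than the {n_tests} tests performed")

    results = []
    for line in test_names:
        labels, tracks = lines[line]
        for action in dictionary.names:
            k_t, n_t = window_counts(labels, tracks, action, window)
            k_c, n_c = window_counts(control_labels, control_tracks, action, window)
            if n_t == 0 or n_c == 0:
                results.append(ComparisonResult(line, action, k_t, n_t, k_c, n_c,
                                                float("nan"), float("nan"),
                                                float("nan"), "untestable"))
                continue
            chi2, p = chi2_compare((k_t, n_t), (k_c, n_c),
                                   continuity_correction=continuity_correction)
            p_corr = min(1.0, multiplier * p)
            if p_corr < alpha:
                outcome = "positive" if k_t / n_t > k_c / n_c else "negative"
            else:
                outcome = "none"
            results.append(ComparisonResult(line, action, k_t, n_t, k_c, n_c,
                                            chi2, p, p_corr, outcome))
    return results


def agreement(
    reference: dict, candidate: dict
) -> AgreementSummary:
    """Concordance of three-level outcomes between two taggers.

    Both maps share the same comparison keys and take values in
    {positive, negative, none}. ``effect_lost`` counts reference effects the
    candidate missed, ``effect_gained`` candidate effects absent from the
    reference, ``opposite`` sign flips.
    """
    if set(reference) != set(candidate):
        missing = sorted(set(reference) ^ set(candidate))
        raise ValueError(f"comparison keys differ between taggers: {missing}")
    concordant = lost = gained = opposite = 0
    for key, ref in reference.items():
        cand = candidate[key]
        if ref == cand:
            concordant += 1
        elif ref != "none" and cand == "none":
            lost += 1
        elif ref == "none" and cand != "none":
            gained += 1
        else:
            opposite += 1
    return AgreementSummary(concordant, lost, gained, opposite)


def macro_f1(true_labels, predicted_labels, dictionary: ActionDictionary) -> float:
    """Unweighted mean of per-class f1 scores.

    Entries untagged in either sequence (None, empty string, or -1) are
    excluded pairwise; classes absent from both truth and prediction are
    excluded from the mean. Invariant to class order in the dictionary.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")

    def resolve(value):
        if value is None or value == "" or (isinstance(value, (int, np.integer)) and value < 0):
            return None
        if isinstance(value, (int, np.integer)):
            return dictionary.names[value]
        return str(value)

    pairs = [(resolve(t), resolve(p)) for t, p in zip(true_labels, predicted_labels)]
    pairs = [(t, p) for t, p in pairs if t is not None and p is not None]
    if not pairs:
        raise ValueError("no tagged pairs left after exclusion")
    y_true = [t for t, _ in pairs]
    y_pred = [p for _, p in pairs]
    present = sorted(set(y_true) | set(y_pred), key=dictionary.names.index)
    return float(f1_score(y_true, y_pred, labels=present, average="macro",
                          zero_division=0))
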