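"""Multi-annotator agreement statistics for slide-level labels.

Histologic-pattern labels have no ground truth — they are subjective
pathologist calls — so model quality is measured as inter-rater
agreement against several annotators.  With four annotation sets (three
pathologists plus the model) the machinery here computes, for every
pair: Cohen's kappa on predominant labels (kappa_predom), the fraction
of slides with matching predominant labels, and per-pattern detection
kappas (pattern present anywhere in the label, predominant or minor,
versus absent).  Per-annotator summaries average an annotator's three
pairwise values; "robust agreement" is the fraction of slides where an
annotator's predominant call matches at least two of the three others.

Cohen's kappa is chance-corrected agreement,

    kappa = (p_o - p_e) / (1 - p_e),

with p_o the observed agreement and p_e the agreement expected from the
raters' marginal label frequencies.  When both raters are constant the
formula is 0/0; by convention the value is 1 if the constant labels
match and 0 otherwise (flagged in reports).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .patterns import CANCER_CLASSES, PatternClass, SlideLabel


@dataclass
class AnnotationSet:
    """One annotator's slide labels, keyed by slide id."""

    annotator_id: str
    labels: Dict[str, SlideLabel]

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)

    @property
    def slide_ids(self) -> frozenset:
        return frozenset(self.labels)


def _check_aligned(a: "AnnotationSet", b: "AnnotationSet") -> List[str]:
    if a.slide_ids != b.slide_ids:
        raise ValueError(
            f"annotators {a.annotator_id!r} and {b.annotator_id!r} "
            "label different slide sets"
        )
    return sorted(a.slide_ids)


def cohens_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> float:
    """Cohen's kappa between two aligned categorical sequences.

    Degenerate case (both sequences constant): 1.0 if they agree, 0.0 if
    not — the formula itself is indeterminate there.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label sequences")
    p_o = sum(x == y for x, y in zip(labels_a, labels_b)) / n
    marg_a = Counter(labels_a)
    marg_b = Counter(labels_b)
    p_e = sum(marg_a[k] * marg_b.get(k, 0) for k in marg_a) / (n * n)
    if p_e >= 1.0 - 1e-15:  # both raters constant
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def predominant_sequence(a: AnnotationSet, slide_ids: Sequence[str]) -> List[str]:
    return [a.labels[s].predominant_name for s in slide_ids]


def predominant_kappa(a: AnnotationSet, b: AnnotationSet) -> float:
    """kappa_predom: Cohen's kappa on predominant labels only."""
    ids = _check_aligned(a, b)
    return cohens_kappa(predominant_sequence(a, ids), predominant_sequence(b, ids))


def predominant_agreement(a: AnnotationSet, b: AnnotationSet) -> float:
    """Fraction of slides on which the two predominant labels match."""
    ids = _check_aligned(a, b)
    sa, sb = predominant_sequence(a, ids), predominant_sequence(b, ids)
    return sum(x == y for x, y in zip(sa, sb)) / len(ids)


def per_class_detection_kappa(
    a: AnnotationSet, b: AnnotationSet, pattern: PatternClass
) -> float:
    """Kappa for detecting a pattern anywhere in the label (predominant or minor)."""
    if not pattern.is_cancer:
        raise ValueError("detection kappa is defined for cancer patterns only")
    ids = _check_aligned(a, b)
    pres_a = [pattern in a.labels[s].patterns for s in ids]
    pres_b = [pattern in b.labels[s].patterns for s in ids]
    return cohens_kappa(pres_a, pres_b)


def robust_agreement(target: AnnotationSet, others: Sequence[AnnotationSet]) -> float:
    """Fraction of slides where the target matches >= 2 of the 3 other annotators."""
    if len(others) != 3:
        raise ValueError(f"robust agreement needs exactly 3 others, got {len(others)}")
    ids = sorted(target.slide_ids)
    for o in others:
        _check_aligned(target, o)
    hits = 0
    for s in ids:
        t = target.labels[s].predominant_name
        matches = sum(o.labels[s].predominant_name == t for o in others)
        hits += matches >= 2
    return hits / len(ids)


def robust_agreement_indicators(
    target: AnnotationSet, others: Sequence[AnnotationSet]
) -> np.ndarray:
    """Per-slide 0/1 indicators underlying robust_agreement (for t-tests/CIs)."""
    ids = sorted(target.slide_ids)
    out = []
    for s in ids:
        t = target.labels[s].predominant_name
        out.append(int(sum(o.labels[s].predominant_name == t for o in others) >= 2))
    return np.asarray(out)


def proportion_ci(p: float, n: int, alpha: float = 0.05, exact: bool = False) -> Tuple[float, float]:
    """95% CI for a proportion: normal approximation, or Clopper-Pearson.

    At p in {0, 1} the normal interval degenerates to a point; request
    ``exact=True`` for a Clopper-Pearson interval there.
    """
    if n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    if exact:
        k = int(round(p * n))
        lo = 0.0 if k == 0 else sps.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else sps.beta.isf(alpha / 2, k + 1, n - k)
        return float(lo), float(hi)
    z = sps.norm.isf(alpha / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return float(p - half), float(p + half)


def kappa_bootstrap_ci(
    labels_a: Sequence[Hashable],
    labels_b: Sequence[Hashable],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for Cohen's kappa, resampling slides."""
    a = list(labels_a)
    b = list(labels_b)
    n = len(a)
    if n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    vals = np.empty(n_boot)
    for i in range(n_boot):
        sel = idx[i]
        vals[i] = cohens_kappa([a[j] for j in sel], [b[j] for j in sel])
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def confidence_interval(
    metric_value: float,
    n: int,
    kind: str = "proportion",
    labels: Optional[Tuple[Sequence, Sequence]] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> Tuple[float, float]:
    """95% CI: normal approximation for proportions, bootstrap for kappas."""
    if kind == "proportion":
        return proportion_ci(metric_value, n)
    if kind == "kappa":
        if labels is None:
            raise ValueError("kappa CI requires the underlying label sequences")
        return kappa_bootstrap_ci(labels[0], labels[1], n_boot=n_boot, seed=seed)
    raise ValueError(f"unknown CI kind {kind!r}")


def compare_metrics(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sample t-test on per-slide indicator sequences.

    Returns (t statistic, two-sided p-value).  When both sequences have
    zero variance the test is degenerate: p = 1 (equal means) or p = 0
    (different means), flagged by t = 0 / inf.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sequence")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class PairwiseAgreement:
    """Agreement statistics for one annotator pair (symmetric)."""

    pair: Tuple[str, str]
    kappa_predom: float
    predominant_agreement: float
    per_class_kappa: Dict[PatternClass, float]


@dataclass
class AgreementReport:
    """The full four-annotator comparison (pairwise matrix plus summaries)."""

    annotators: List[str]
    pairwise: Dict[Tuple[str, str], PairwiseAgreement]
    average_kappa: Dict[str, float]
    average_agreement: Dict[str, float]
    robust: Dict[str, float]
    inter_pathologist_kappa: Optional[float]
    inter_pathologist_agreement: Optional[float]
    kappa_ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    agreement_ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    robust_ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    n_slides: int = 0

    def pair(self, a: str, b: str) -> PairwiseAgreement:
        key = tuple(sorted((a, b)))
        return self.pairwise[key]

    def to_frame(self) -> pd.DataFrame:
        """Summary table: one row per annotator plus the inter-pathologist row."""
        rows = []
        for ann in self.annotators:
            rows.append(
                {
                    "annotator": ann,
                    "average_kappa": self.average_kappa[ann],
                    "kappa_ci_low": self.kappa_ci.get(ann, (np.nan, np.nan))[0],
                    "kappa_ci_high": self.kappa_ci.get(ann, (np.nan, np.nan))[1],
                    "average_agreement": self.average_agreement[ann],
                    "agreement_ci_low": self.agreement_ci.get(ann, (np.nan, np.nan))[0],
                    "agreement_ci_high": self.agreement_ci.get(ann, (np.nan, np.nan))[1],
                    "robust_agreement": self.robust[ann],
                    "robust_ci_low": self.robust_ci.get(ann, (np.nan, np.nan))[0],
                    "robust_ci_high": self.robust_ci.get(ann, (np.nan, np.nan))[1],
                }
            )
        if self.inter_pathologist_kappa is not None:
            rows.append(
                {
                    "annotator": "inter-pathologist",
                    "average_kappa": self.inter_pathologist_kappa,
                    "average_agreement": self.inter_pathologist_agreement,
                }
            )
        return pd.DataFrame(rows)

    def kappa_matrix(self) -> pd.DataFrame:
        """Symmetric pairwise kappa_predom matrix (diagonal NaN)."""
        names = self.annotators
        m = pd.DataFrame(np.nan, index=names, columns=names)
        for (a, b), pw in self.pairwise.items():
            m.loc[a, b] = m.loc[b, a] = pw.kappa_predom
        return m

    def agreement_matrix(self) -> pd.DataFrame:
        names = self.annotators
        m = pd.DataFrame(np.nan, index=names, columns=names)
        for (a, b), pw in self.pairwise.items():
            m.loc[a, b] = m.loc[b, a] = pw.predominant_agreement
        return m

    def to_dict(self) -> dict:
        return {
            "annotators": self.annotators,
            "n_slides": self.n_slides,
            "pairwise": {
                f"{a}|{b}": {
                    "kappa_predom": pw.kappa_predom,
                    "predominant_agreement": pw.predominant_agreement,
                    "per_class_kappa": {
                        c.label: v for c, v in pw.per_class_kappa.items()
                    },
                }
                for (a, b), pw in self.pairwise.items()
            },
            "average_kappa": self.average_kappa,
            "average_agreement": self.average_agreement,
            "robust_agreement": self.robust,
            "inter_pathologist_kappa": self.inter_pathologist_kappa,
            "inter_pathologist_agreement": self.inter_pathologist_agreement,
            "kappa_ci": {k: list(v) for k, v in self.kappa_ci.items()},
            "agreement_ci": {k: list(v) for k, v in self.agreement_ci.items()},
            "robust_ci": {k: list(v) for k, v in self.robust_ci.items()},
        }


def average_metrics(
    all_sets: Sequence[AnnotationSet],
    pathologist_ids: Optional[Sequence[str]] = None,
    with_ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
    strict_four: bool = True,
) -> AgreementReport:
    """Pairwise agreement statistics and per-annotator averages.

    The canonical setting is four annotation sets (three pathologists plus
    the model); ``strict_four=False`` generalizes to n annotators.  Each
    annotator's average kappa/agreement is the mean of its pairwise values
    against the others; the inter-pathologist row averages the
    pathologist-pathologist pairs.  Robust agreement requires exactly four
    sets and is skipped otherwise.
    """
    if strict_four and len(all_sets) != 4:
        raise ValueError(f"expected exactly 4 annotation sets, got {len(all_sets)}")
    if len(all_sets) < 2:
        raise ValueError("need at least 2 annotation sets")
    names = [s.annotator_id for s in all_sets]
    if len(set(names)) != len(names):
        raise ValueError("annotator ids must be unique")
    by_name = {s.annotator_id: s for s in all_sets}
    ids = sorted(all_sets[0].slide_ids)
    for s in all_sets[1:]:
        _check_aligned(all_sets[0], s)
    n = len(ids)

    pairwise: Dict[Tuple[str, str], PairwiseAgreement] = {}
    for i, a in enumerate(all_sets):
        for b in all_sets[i + 1 :]:
            key = tuple(sorted((a.annotator_id, b.annotator_id)))
            pairwise[key] = PairwiseAgreement(
                pair=key,
                kappa_predom=predominant_kappa(a, b),
                predominant_agreement=predominant_agreement(a, b),
                per_class_kappa={
                    c: per_class_detection_kappa(a, b, c) for c in CANCER_CLASSES
                },
            )

    def _pairs_of(name: str) -> List[PairwiseAgreement]:
        return [pw for key, pw in pairwise.items() if name in key]

    average_kappa = {
        name: float(np.mean([pw.kappa_predom for pw in _pairs_of(name)]))
        for name in names
    }
    average_agreement = {
        name: float(np.mean([pw.predominant_agreement for pw in _pairs_of(name)]))
        for name in names
    }

    robust: Dict[str, float] = {}
    if len(all_sets) == 4:
        for name in names:
            others = [by_name[o] for o in names if o != name]
            robust[name] = robust_agreement(by_name[name], others)

    if pathologist_ids is None:
        pathologist_ids = names[:-1] if len(all_sets) == 4 else []
    path_pairs = [
        pw
        for key, pw in pairwise.items()
        if key[0] in pathologist_ids and key[1] in pathologist_ids
    ]
    inter_k = float(np.mean([pw.kappa_predom for pw in path_pairs])) if path_pairs else None
    inter_a = (
        float(np.mean([pw.predominant_agreement for pw in path_pairs]))
        if path_pairs
        else None
    )

    kappa_ci: Dict[str, Tuple[float, float]] = {}
    agreement_ci: Dict[str, Tuple[float, float]] = {}
    robust_ci: Dict[str, Tuple[float, float]] = {}
    if with_ci and n >= 2:
        for name in names:
            # bootstrap the averaged kappa by resampling slides once for all pairs
            others = [o for o in names if o != name]
            seqs = {
                o: (
                    predominant_sequence(by_name[name], ids),
                    predominant_sequence(by_name[o], ids),
                )
                for o in others
            }
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, n, size=(n_boot, n))
            vals = np.empty(n_boot)
            for i in range(n_boot):
                sel = idx[i]
                ks = [
                    cohens_kappa(
                        [sa[j] for j in sel], [sb[j] for j in sel]
                    )
                    for sa, sb in seqs.values()
                ]
                vals[i] = np.mean(ks)
            lo, hi = np.percentile(vals, [2.5, 97.5])
            kappa_ci[name] = (float(lo), float(hi))
            agreement_ci[name] = proportion_ci(average_agreement[name], n)
            if name in robust:
                robust_ci[name] = proportion_ci(robust[name], n)

    return AgreementReport(
        annotators=names,
        pairwise=pairwise,
        average_kappa=average_kappa,
        average_agreement=average_agreement,
        robust=robust,
        inter_pathologist_kappa=inter_k,
        inter_pathologist_agreement=inter_a,
        kappa_ci=kappa_ci,
        agreement_ci=agreement_ci,
        robust_ci=robust_ci,
        n_slides=n,
    )


def render_agreement_heatmaps(report: AgreementReport, path) -> None:
    """Side-by-side pairwise kappa and agreement matrices as a PNG figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    for ax, (title, matrix) in zip(
        axes,
        [
            ("pairwise kappa (predominant)", report.kappa_matrix()),
            ("pairwise agreement (predominant)", report.agreement_matrix()),
        ],
    ):
        im = ax.imshow(matrix.values, vmin=-1 if matrix.min().min() < 0 else 0, vmax=1)
        ax.set_xticks(range(len(matrix)), matrix.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(matrix)), matrix.index)
        for i in range(len(matrix)):
            for j in range(len(matrix)):
                v = matrix.values[i, j]
                if np.isfinite(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=9)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_annotation_csv(path) -> List[AnnotationSet]:
    """Load annotation sets from CSV (slide_id, annotator, predominant, minors).

    Minors are semicolon-delimited class names; empty means none.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    sets: Dict[str, Dict[str, SlideLabel]] = {}
    for _, row in df.iterrows():
        minors = frozenset(
            PatternClass.from_label(m)
            for m in str(row["minors"]).split(";")
            if m.strip()
        )
        pred = row["predominant"].strip().lower()
        label = SlideLabel(
            None if pred in ("", "benign") else PatternClass.from_label(pred),
            minors if pred not in ("", "benign") else frozenset(),
        )
        sets.setdefault(row["annotator"], {})[row["slide_id"]] = label
    return [AnnotationSet(ann, labels) for ann, labels in sorted(sets.items())]


def write_annotation_csv(sets: Sequence[AnnotationSet], path) -> None:
    rows = []
    for s in sets:
        for slide_id, label in sorted(s.labels.items()):
            rows.append(
                {
                    "slide_id": slide_id,
                    "annotator": s.annotator_id,
                    "predominant": label.predominant_name,
                    "minors": ";".join(sorted(m.label for m in label.minors)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
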