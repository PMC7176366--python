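"""Habitat ontology, cohort construction and Mann-Whitney comparisons.

Metagenome samples carry a two-level habitat ontology path (level 1 is a
closed vocabulary: aquatic, terrestrial, engineered, host_associated),
per-sample taxon relative abundances and assembled depth.  The module
tallies habitat distributions of anchor-positive samples and compares a
positive cohort against aquatic and terrestrial anchor-negative cohorts
with the two-sided Mann-Whitney U test (exact for small tie-free
samples, tie-corrected normal approximation with continuity correction
otherwise).

No multiple-testing correction is applied across the comparisons; raw
p-values are reported, with the sidedness and tie-handling decisions
recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

LEVEL1_CATEGORIES = ("aquatic", "terrestrial", "engineered", "host_associated")

EXACT_MAX_N = 20  # exact enumeration cutoff for the U test


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class HabitatRecord:
    """One metagenome sample's metadata."""

    sample_id: str
    ontology_path: tuple[str, ...]
    depth_bp: float
    abundance: Mapping[str, float]
    anchor_positive: bool

    def __post_init__(self) -> None:
        if not self.ontology_path or self.ontology_path[0] not in LEVEL1_CATEGORIES:
            raise StatsError(
                f"sample {self.sample_id!r}: ontology level 1 must be one of {LEVEL1_CATEGORIES}"
            )
        if self.depth_bp < 0:
            raise StatsError(f"sample {self.sample_id!r}: negative depth")
        for taxon, frac in self.abundance.items():
            if not (0.0 <= frac <= 1.0):
                raise StatsError(
                    f"sample {self.sample_id!r}: abundance of {taxon!r} outside [0, 1]"
                )

    def category(self, level: int) -> str:
        """Ontology category at ``level`` (1-based); deepest available if shallower."""
        idx = min(level, len(self.ontology_path)) - 1
        return self.ontology_path[idx]


def load_ontology(path: str | Path | None = None) -> dict[str, list[str]]:
    """The shipped two-level habitat vocabulary (extendable YAML)."""
    if path is None:
        path = Path(str(resources.files("abyssminer") / "data" / "habitat_ontology.yaml"))
    with open(path) as fh:
        return yaml.safe_load(fh)


def tally_distribution(
    records: Iterable[HabitatRecord],
    level: int = 2,
    predicate: Callable[[HabitatRecord], bool] | None = None,
) -> dict[str, tuple[int, float]]:
    """Category -> (count, fraction) over the filtered records.

    Fractions sum to 1 (zero-count categories are omitted); rounding is
    left to presentation.  Raises with a message distinguishing an empty
    record set from a filter that matched nothing.
    """
    records = list(records)
    if not records:
        raise StatsError("no habitat records supplied")
    selected = [r for r in records if predicate is None or predicate(r)]
    if not selected:
        raise StatsError("no records match the filter (the record set itself is non-empty)")
    counts: dict[str, int] = {}
    for r in selected:
        cat = r.category(level)
        counts[cat] = counts.get(cat, 0) + 1
    total = len(selected)
    return {cat: (n, n / total) for cat, n in sorted(counts.items())}


@dataclass(frozen=True)
class UTestResult:
    U: float
    n1: int
    n2: int
    method: str  # exact | normal_tie_corrected
    p_two_sided: float
    z: float | None = None

    def swapped(self) -> "UTestResult":
        return UTestResult(
            U=self.n1 * self.n2 - self.U,
            n1=self.n2,
            n2=self.n1,
            method=self.method,
            p_two_sided=self.p_two_sided,
            z=None if self.z is None else -self.z,
        )


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    U is computed from midranks of the pooled sample.  The exact p-value
    (full enumeration of the null rank distribution) is used whenever
    max(n1, n2) <= 20 and the pooled values are tie-free; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.  ``method`` may force ``"exact"`` or
    ``"normal_tie_corrected"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    U = r1 - n1 * (n1 + 1) / 2.0

    ties = _has_ties(pooled)
    if method == "auto":
        method = "exact" if (max(n1, n2) <= EXACT_MAX_N and not ties) else "normal_tie_corrected"
    if method == "exact" and ties:
        raise StatsError("exact method is only defined for tie-free samples")

    if method == "exact":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return UTestResult(U=U, n1=n1, n2=n2, method="exact", p_two_sided=float(res.pvalue))

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0.0:
        # all pooled values identical: no evidence either way
        return UTestResult(U=U, n1=n1, n2=n2, method="normal_tie_corrected", p_two_sided=1.0, z=0.0)
    diff = U - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return UTestResult(U=U, n1=n1, n2=n2, method="normal_tie_corrected", p_two_sided=p, z=float(z))


DEFAULT_VARIABLES = ("Bacteria", "Actinobacteria", "depth_bp")
DEFAULT_STRATA = ("aquatic", "terrestrial")


def _variable_values(records: Sequence[HabitatRecord], variable: str) -> np.ndarray:
    if variable == "depth_bp":
        return np.array([r.depth_bp for r in records], dtype=float)
    return np.array([r.abundance.get(variable, 0.0) for r in records], dtype=float)


@dataclass
class CohortComparison:
    stratum: str
    variable: str
    test: UTestResult
    median_positive: float
    median_negative: float


@dataclass
class CohortReport:
    seed: int
    positives_n: int
    negatives_per_stratum: int
    positive_ids: list[str]
    negative_ids: dict[str, list[str]]
    comparisons: list[CohortComparison]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "positives_n": self.positives_n,
            "negatives_per_stratum": self.negatives_per_stratum,
            "positive_ids": self.positive_ids,
            "negative_ids": self.negative_ids,
            "metadata": self.metadata,
            "comparisons": [
                {
                    "stratum": c.stratum,
                    "variable": c.variable,
                    "U": c.test.U,
                    "n1": c.test.n1,
                    "n2": c.test.n2,
                    "method": c.test.method,
                    "p_two_sided": c.test.p_two_sided,
                    "median_positive": c.median_positive,
                    "median_negative": c.median_negative,
                }
                for c in self.comparisons
            ],
        }


def compare_cohorts(
    records: Iterable[HabitatRecord],
    positives_n: int = 50,
    negatives_per_stratum: int = 50,
    strata: Sequence[str] = DEFAULT_STRATA,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    seed: int = 0,
) -> CohortReport:
    """Positive-vs-negative cohort comparison across strata and variables.

    ``positives_n`` anchor-positive samples and ``negatives_per_stratum``
    anchor-negative samples per habitat stratum are drawn without
    replacement (seeded); each (stratum, variable) pair gets one U test
    plus group medians.
    """
    records = list(records)
    rng = np.random.default_rng(seed)
    positives = [r for r in records if r.anchor_positive]
    if len(positives) < positives_n:
        raise StatsError(
            f"requested {positives_n} positive samples but only {len(positives)} available"
        )
    pos_sample = [positives[i] for i in rng.choice(len(positives), positives_n, replace=False)]
    neg_samples: dict[str, list[HabitatRecord]] = {}
    for stratum in strata:
        pool = [r for r in records if not r.anchor_positive and r.category(1) == stratum]
        if len(pool) < negatives_per_stratum:
            raise StatsError(
                f"stratum {stratum!r}: requested {negatives_per_stratum} negative samples "
                f"but only {len(pool)} available"
            )
        neg_samples[stratum] = [
            pool[i] for i in rng.choice(len(pool), negatives_per_stratum, replace=False)
        ]
    comparisons: list[CohortComparison] = []
    for stratum in strata:
        for variable in variables:
            xv = _variable_values(pos_sample, variable)
            yv = _variable_values(neg_samples[stratum], variable)
            comparisons.append(
                CohortComparison(
                    stratum=stratum,
                    variable=variable,
                    test=mann_whitney_u(xv, yv),
                    median_positive=float(np.median(xv)),
                    median_negative=float(np.median(yv)),
                )
            )
    return CohortReport(
        seed=seed,
        positives_n=positives_n,
        negatives_per_stratum=negatives_per_stratum,
        positive_ids=[r.sample_id for r in pos_sample],
        negative_ids={s: [r.sample_id for r in neg_samples[s]] for s in strata},
        comparisons=comparisons,
        metadata={
            "alternative": "two-sided",
            "exact_cutoff_max_n": EXACT_MAX_N,
            "continuity_correction": True,
            "multiple_testing_correction": "none (raw p-values)",
        },
    )


METADATA_COLUMNS = (
    "sample_id",
    "level1",
    "level2",
    "depth_bp",
    "abund_bacteria",
    "abund_actinobacteria",
    "anchor_positive",
)


def read_metadata_tsv(path: str | Path) -> list[HabitatRecord]:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise StatsError(f"{path}: missing metadata columns {missing}")
    records = []
    for row in table.itertuples(index=False):
        records.append(
            HabitatRecord(
                sample_id=str(row.sample_id),
                ontology_path=(str(row.level1), str(row.level2)),
                depth_bp=float(row.depth_bp),
                abundance={
                    "Bacteria": float(row.abund_bacteria),
                    "Actinobacteria": float(row.abund_actinobacteria),
                },
                anchor_positive=bool(row.anchor_positive)
                if not isinstance(row.anchor_positive, str)
                else row.anchor_positive.lower() in ("1", "true", "yes"),
            )
        )
    return records


def write_metadata_tsv(records: Iterable[HabitatRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "level1": r.ontology_path[0],
            "level2": r.ontology_path[1] if len(r.ontology_path) > 1 else "",
            "depth_bp": r.depth_bp,
            "abund_bacteria": r.abundance.get("Bacteria", 0.0),
            "abund_actinobacteria": r.abundance.get("Actinobacteria", 0.0),
            "anchor_positive": int(r.anchor_positive),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
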