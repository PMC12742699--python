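"""Mimic-model co-occurrence analysis.

Each site carries one focal Colobopsis class -- the monomorphic species
(``truncata``) or one of the three color morphs of its polymorphic sister
species -- and presence/absence flags for four putative model species. For
every model the sites split into a "mimic" group (the classes hypothesised to
imitate that model) and the rest, giving a 2x2 table of mimic-group membership
against model presence. Association is tested with Fisher's exact test;
family-wise error over the four models is controlled by the Holm step-down
correction.

The exact test is computed in log-space over the hypergeometric support. The
default two-sided convention sums all tables (with the observed margins) whose
point probability does not exceed the observed one; one-sided and
double-the-smaller-tail alternatives are available. The directional
("greater") test is the convention of the published association table, since
the mimicry hypothesis predicts an excess, not a deficit, of co-occurrence.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

#: Model species columns of a site table.
MODELS = ["Do_quadripunctatus", "Cr_scutellaris", "Cr_schmidti", "Cr_ionia_sl"]

#: Focal classes: the monomorphic species plus the three morphs of its sister.
CLASSES = [
    "truncata", "imitans_truncata_like", "imitans_red_headed", "imitans_blackish",
]

#: Which classes are hypothesised to mimic each model.
MIMIC_GROUPS = {
    "Do_quadripunctatus": {"truncata", "imitans_truncata_like"},
    "Cr_schmidti": {"truncata", "imitans_truncata_like"},
    "Cr_scutellaris": {"imitans_red_headed"},
    "Cr_ionia_sl": {"imitans_blackish"},
}


@dataclass
class AssociationTable:
    """A mimic-group x model-presence 2x2 table with its exact test."""

    model_name: str
    a: int  # mimic sites, model present
    b: int  # mimic sites, model absent
    c: int  # non-mimic sites, model present
    d: int  # non-mimic sites, model absent
    p_raw: float = np.nan
    p_holm: float = np.nan

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else np.nan
        return (self.a * self.d) / (self.b * self.c)


def published_site_counts() -> pd.DataFrame:
    """Class-level site counts of the published co-occurrence survey.

    One row per focal class: the number of surveyed sites and, per model
    species, at how many of them that model is present.
    """
    src = importlib.resources.files("ncmorph.data").joinpath("mimicry_site_counts.csv")
    with importlib.resources.as_file(src) as path:
        return pd.read_csv(path)


def sites_from_class_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand class-level counts into a per-site presence/absence table.

    Only the class-by-model margins are published, not the joint pattern of
    the four models within a class, so the expansion marks the model present
    at the first ``n_present`` sites of each class (a synthetic joint
    structure). Every 2x2 mimic-model analysis depends on the margins alone,
    which the expansion reproduces exactly.
    """
    rows = []
    for rec in counts.itertuples():
        for i in range(int(rec.n_sites)):
            row = {"site_id": f"{rec.colobopsis_class}_{i + 1:02d}",
                   "colobopsis_class": rec.colobopsis_class}
            for model in MODELS:
                row[model] = int(i < int(getattr(rec, model)))
            rows.append(row)
    return pd.DataFrame(rows)


def class_counts(sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse a site table back to class-level presence counts."""
    grouped = sites.groupby("colobopsis_class", sort=False)
    out = grouped[MODELS].sum().astype(int)
    out.insert(0, "n_sites", grouped.size())
    return out.reset_index()


def build_2x2(sites: pd.DataFrame, model_name: str,
              mimic_classes=None) -> AssociationTable:
    """Count the mimic-group x model-presence 2x2 table for one model."""
    if model_name not in MODELS:
        raise ValueError(f"unknown model {model_name!r}; expected one of {MODELS}")
    if mimic_classes is None:
        mimic_classes = MIMIC_GROUPS[model_name]
    mimic_classes = set(mimic_classes)
    known = set(sites["colobopsis_class"].unique())
    if not mimic_classes or not (known - mimic_classes):
        raise ValueError("mimic classes must be a nonempty strict subset of the "
                         "classes present")
    is_mimic = sites["colobopsis_class"].isin(mimic_classes)
    present = sites[model_name].astype(bool)
    return AssociationTable(
        model_name=model_name,
        a=int((is_mimic & present).sum()), b=int((is_mimic & ~present).sum()),
        c=int((~is_mimic & present).sum()), d=int((~is_mimic & ~present).sum()),
    )


def _log_hypergeom_pmf(support: np.ndarray, n1: int, n2: int, k: int) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeom(N=n1+n2, K=k, n=n1) over ``support``."""
    x = support
    return (gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
            + gammaln(n2 + 1) - gammaln(k - x + 1) - gammaln(n2 - (k - x) + 1)
            - (gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1)))


def fisher_exact(a: int, b: int, c: int, d: int,
                 alternative: str = "two-sided") -> float:
    """Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    With both row margins fixed, cell ``a`` follows a hypergeometric law.
    ``alternative``:

    - ``"two-sided"`` (default): minimum-likelihood rule -- the sum of the
      probabilities of all tables with the same margins whose point
      probability is <= the observed one (within relative tolerance 1e-7).
    - ``"two-sided-doubling"``: twice the smaller tail, capped at 1.
    - ``"greater"`` / ``"less"``: one-sided tails on ``a``.

    All probabilities are accumulated in log-space.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be nonnegative integers")
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("a zero row margin leaves the test undefined")
    k = a + c
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, n1, n2, k)
    log_obs = logp[a - lo]
    if alternative == "greater":
        tail = logp[support >= a]
    elif alternative == "less":
        tail = logp[support <= a]
    elif alternative == "two-sided":
        tail = logp[logp <= log_obs + np.log1p(1e-7)]
    elif alternative == "two-sided-doubling":
        left = _logsumexp(logp[support <= a])
        right = _logsumexp(logp[support >= a])
        return float(min(1.0, 2.0 * np.exp(min(left, right))))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, np.exp(_logsumexp(tail))))


def _logsumexp(logs: np.ndarray) -> float:
    m = np.max(logs)
    return float(m + np.log(np.sum(np.exp(logs - m))))


def holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    The i-th smallest p is multiplied by (m - i), then a running maximum
    enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def table3_report(sites: pd.DataFrame, alternative: str = "greater",
                  alpha: float = 0.05):
    """Full association report over the four model species.

    Returns ``(class_block, tests)``: the class-level presence/absence counts
    and one row per model with the mimic/non-mimic sums, the exact p
    (directional by default -- the mimicry hypothesis predicts excess
    co-occurrence), the Holm-adjusted p over the four tests, and a
    significance flag at ``alpha``.
    """
    tables = [build_2x2(sites, model) for model in MODELS]
    degenerate = [t for t in tables if (t.a + t.b == 0) or (t.c + t.d == 0)]
    if degenerate:
        raise ValueError(
            f"degenerate margin (all or no sites in the mimic group) for "
            f"{[t.model_name for t in degenerate]}"
        )
    p_raw = [fisher_exact(t.a, t.b, t.c, t.d, alternative) for t in tables]
    p_adj = holm(p_raw)
    for t, pr, pa in zip(tables, p_raw, p_adj):
        t.p_raw, t.p_holm = pr, pa
    tests = pd.DataFrame([
        {"model": t.model_name, "mimic_present": t.a, "mimic_absent": t.b,
         "nonmimic_present": t.c, "nonmimic_absent": t.d,
         "odds_ratio": t.odds_ratio, "p_raw": t.p_raw, "p_holm": t.p_holm,
         "significant": t.p_holm < alpha}
        for t in tables
    ])
    return class_counts(sites), tests
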