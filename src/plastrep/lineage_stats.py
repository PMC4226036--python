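"""Lineage-level repeat statistics.

Three questions are asked of a panel of genome repeat profiles:

* Do lineages differ in whether tandem or inverted repeats predominate?
  (Fisher's exact test on a 2x2 table of group x tandem-majority.)
* Does repeat number or size scale with genome size or intergenic room?
  (Per-group ordinary least-squares regressions.)
* How far apart are genes on average? (Mean intergenic distance around the
  circle, the predictor used by the regressions.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import AnnotatedGenome, Group
from .repeats import GenomeRepeatProfile

RESPONSES = ("n_repeats", "mean_repeat_size")
PREDICTORS = ("genome_size", "mean_intergenic")


def mean_intergenic_distance(g: AnnotatedGenome) -> float:
    """Mean gap between consecutive feature boundaries around the genome.

    Gaps are measured between one feature's end and the next feature's start;
    on circular genomes the last feature wraps to the first. Negative gaps from
    overlapping features clamp to 0. Raises ValueError with < 2 features.
    """
    feats = sorted(g.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        raise ValueError("mean intergenic distance undefined with < 2 features")
    gaps = [max(0, b.start - a.end) for a, b in zip(feats, feats[1:])]
    if g.circular:
        wrap = feats[0].start + g.length - feats[-1].end
        gaps.append(max(0, wrap))
    return float(np.mean(gaps))


@dataclass
class RegressionResult:
    response: str
    predictor: str
    group: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class LineageComparison:
    """2x2 tandem-majority contingency (rows = groups) plus its Fisher p,
    and any per-group regressions attached afterwards."""

    groups: tuple[str, str]
    contingency: np.ndarray  # rows: groups; cols: (tandem-majority, not)
    fisher_p: float
    regressions: dict[tuple, RegressionResult] = field(default_factory=dict)


def tandem_majority_table(
    profiles: list[GenomeRepeatProfile], group_a: Group | str, group_b: Group | str
) -> np.ndarray:
    """Rows = (group_a, group_b); columns = (tandem-majority, not).

    A genome is tandem-majority when n_tandem strictly exceeds n_inverted;
    ties count as not tandem-majority.
    """
    ga, gb = Group(group_a), Group(group_b)
    table = np.zeros((2, 2), dtype=int)
    for prof in profiles:
        if prof.group == ga:
            row = 0
        elif prof.group == gb:
            row = 1
        else:
            continue
        table[row, 0 if prof.tandem_majority else 1] += 1
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("each group must contain at least one genome")
    return table


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p: the total hypergeometric probability of all
    tables with the observed margins whose probability does not exceed the
    observed table's."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def fisher_tandem_majority(
    profiles: list[GenomeRepeatProfile], group_a: Group | str, group_b: Group | str
) -> LineageComparison:
    table = tandem_majority_table(profiles, group_a, group_b)
    return LineageComparison(
        groups=(Group(group_a).value, Group(group_b).value),
        contingency=table,
        fisher_p=fisher_exact_2x2(table),
    )


def _profile_value(prof: GenomeRepeatProfile, name: str):
    if name == "n_repeats":
        return prof.n_inverted + prof.n_tandem
    if name == "mean_repeat_size":
        return prof.mean_repeat_size
    if name == "genome_size":
        return prof.genome_size
    if name == "mean_intergenic":
        return prof.mean_intergenic
    raise ValueError(f"unknown profile variable {name!r}")


def regress(
    profiles: list[GenomeRepeatProfile],
    response: str,
    predictor: str,
    group: Group | str | None = None,
) -> RegressionResult:
    """OLS of response on predictor within one group (or the whole panel).

    p-value is the two-sided t-test on the slope. Genomes with an undefined
    response or predictor (e.g. no repeats) are dropped. Requires >= 3 usable
    genomes and a non-constant predictor.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    if predictor not in PREDICTORS:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    grp = Group(group) if group is not None else None
    pairs = []
    for prof in profiles:
        if grp is not None and prof.group != grp:
            continue
        x = _profile_value(prof, predictor)
        y = _profile_value(prof, response)
        if x is None or y is None:
            continue
        pairs.append((float(x), float(y)))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 genomes for regression, got {len(pairs)}")
    x, y = np.array(pairs).T
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        response=response,
        predictor=predictor,
        group=grp.value if grp else "all",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=len(pairs),
    )


def lineage_comparison(
    profiles: list[GenomeRepeatProfile],
    group_a: Group | str = Group.CASH,
    group_b: Group | str = Group.GREEN,
) -> LineageComparison:
    """Fisher test plus the full response x predictor x group regression grid
    (regressions that cannot be computed are skipped)."""
    cmp_ = fisher_tandem_majority(profiles, group_a, group_b)
    for grp in (group_a, group_b):
        for response in RESPONSES:
            for predictor in PREDICTORS:
                try:
                    res = regress(profiles, response, predictor, grp)
                except ValueError:
                    continue
                cmp_.regressions[(response, predictor, Group(grp).value)] = res
    return cmp_


def group_max_repeat_size(profiles: list[GenomeRepeatProfile]) -> dict[str, int | None]:
    """Descriptive group-wise maximum repeat size (the CASH size-cap
    observation is reported, not tested inferentially)."""
    out: dict[str, int | None] = {}
    for prof in profiles:
        key = prof.group.value if isinstance(prof.group, Group) else str(prof.group)
        if prof.max_repeat_size is not None:
            cur = out.get(key)
            out[key] = prof.max_repeat_size if cur is None else max(cur, prof.max_repeat_size)
        else:
            out.setdefault(key, None)
    return out
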