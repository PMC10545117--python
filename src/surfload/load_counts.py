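"""Per-individual deleterious-load counting and among-population tests.

Additive (total) load per individual is N_total = 2*N_homo + N_hetero over
polarized genotypes of one effect class; recessive (fixed) load is N_homo,
the count of homozygous-derived genotypes.  Among-population differences are
tested with a one-way ANOVA followed by Tukey HSD contrasts, Bonferroni
corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class IndividualLoad:
    sample_id: str
    effect_class: str
    n_hom_derived: int
    n_het: int
    sites_used: int

    @property
    def additive(self) -> int:
        return 2 * self.n_hom_derived + self.n_het

    @property
    def recessive(self) -> int:
        return self.n_hom_derived


def individual_load(
    polarized: GenotypeMatrix, effect_class: str
) -> list[IndividualLoad]:
    """Count derived homozygotes and heterozygotes per individual at sites of
    one effect class; missing genotypes are excluded from sites_used."""
    sel = np.array([s.effect_class == effect_class for s in polarized.sites])
    if not sel.any():
        warnings.warn(f"no sites of class {effect_class!r}")
        return [
            IndividualLoad(s, effect_class, 0, 0, 0) for s in polarized.samples
        ]
    g = polarized.genotypes[:, sel]
    nonmiss = g != MISSING
    return [
        IndividualLoad(
            sample,
            effect_class,
            int((g[i] == 2).sum()),
            int((g[i] == 1).sum()),
            int(nonmiss[i].sum()),
        )
        for i, sample in enumerate(polarized.samples)
    ]


def load_table(loads: list[IndividualLoad], popmap: PopulationMap) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [l.sample_id for l in loads],
            "population": [popmap.sample_to_pop.get(l.sample_id) for l in loads],
            "effect_class": [l.effect_class for l in loads],
            "additive": [l.additive for l in loads],
            "recessive": [l.recessive for l in loads],
            "n_het": [l.n_het for l in loads],
            "sites_used": [l.sites_used for l in loads],
        }
    )


def population_load_summary(
    loads: list[IndividualLoad], popmap: PopulationMap, per_site: bool = False
) -> pd.DataFrame:
    """Mean/SD/n of additive and recessive load per population.

    ``per_site=True`` divides each individual's counts by its sites_used
    before aggregating (robustness option for unequal missingness)."""
    df = load_table(loads, popmap)
    if per_site:
        for col in ("additive", "recessive"):
            df[col] = df[col] / df["sites_used"].replace(0, np.nan)
    out = (
        df.groupby(["population", "effect_class"])
        .agg(
            additive_mean=("additive", "mean"),
            additive_sd=("additive", "std"),
            recessive_mean=("recessive", "mean"),
            recessive_sd=("recessive", "std"),
            n=("sample", "size"),
        )
        .reset_index()
    )
    return out


@dataclass
class LoadComparison:
    effect_class: str
    load_type: str  # additive | recessive
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # pair, meandiff, p_tukey, p_adj (Bonferroni)
    degenerate: bool = False


def compare_loads(
    loads: list[IndividualLoad], popmap: PopulationMap, load_type: str = "additive"
) -> LoadComparison:
    """One-way ANOVA of per-individual load across populations, Tukey HSD
    pairwise contrasts, Bonferroni-adjusted."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = load_table(loads, popmap).dropna(subset=["population"])
    effect_class = loads[0].effect_class if loads else "unknown"
    groups = [g[load_type].to_numpy(float) for _, g in df.groupby("population")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 populations with >= 2 individuals")
    if all(np.var(g) == 0 for g in groups):
        pairs = []
        pops = sorted(df.population.unique())
        same = len({g[0] for g in groups}) == 1
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                pairs.append({"group1": a, "group2": b, "meandiff": np.nan,
                              "p_tukey": np.nan, "p_adj": np.nan})
        return LoadComparison(
            effect_class, load_type, 0.0 if same else np.inf,
            1.0 if same else 0.0, pd.DataFrame(pairs), degenerate=True,
        )
    f, p = stats.f_oneway(*groups)
    res = pairwise_tukeyhsd(
        df[load_type].to_numpy(float), df["population"].to_numpy(), alpha=0.05
    )
    pops = list(res.groupsunique)
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    tk = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": np.asarray(res.meandiffs, dtype=float),
            "p_tukey": np.asarray(res.pvalues, dtype=float),
        }
    )
    m = len(tk)
    tk["p_adj"] = np.minimum(tk["p_tukey"] * m, 1.0)
    return LoadComparison(effect_class, load_type, float(f), float(p), tk)
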