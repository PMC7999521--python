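"""Enterotype-structured synthetic cohorts with coupled butyrate phenotypes.

The generator emulates the processed data of a ~105-pig 16S cohort:

* Three latent community types over a 40-genus roster.  Component mean
  profiles plant the study's driver genera — a Lactobacillus/Clostridium
  sensu stricto 1 type (14.39% / 13.41%), a Clostridium sensu stricto 1 /
  Bifidobacterium type (17.49% / 11.78%) and a Bacteroides type (18.17%)
  — with the remaining mass spread geometrically over common swine-gut
  genera.
* Per-sample compositions are Dirichlet-multinomial: proportions drawn
  from Dirichlet(concentration x component profile), counts multinomial
  at a log-uniform sequencing depth in [40,000, 100,000].  A shared
  lognormal latent factor scales the Clostridium sensu stricto 1 /
  Turicibacter / Romboutsia trio together, planting their co-occurrence.
* Fecal butyrate (mg/g) is a linear function of the realized relative
  abundances of six butyrate-producer genera (all elevated in component
  3) plus Gaussian noise, truncated at zero.  Log10 Buk/But gene copies
  are monotone in butyrate with Gaussian noise calibrated so their rank
  correlation with butyrate approaches configurable targets (defaults
  0.7464 for But, 0.4905 for Buk — But being the terminal gene of the
  dominant butyrate-synthesis route).

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, rankdata

from .io_tables import (
    BUK,
    BUT,
    BUTYRATE,
    COUNTS,
    AbundanceTable,
    PhenotypeTable,
)

# Component mean relative abundances per genus (comp1, comp2, comp3).
# Driver-genus values are the per-enterotype means of the emulated
# cohort; the surrounding genera follow the cohort's per-enterotype phylum
# composition (Firmicutes highest in ET1; Actinobacteria, Proteobacteria
# and Acidobacteria enriched in ET2; Bacteroidetes in ET3; Spirochaetes in
# ET1).  An "unclassified" bin absorbs the remaining mass per component.
_SPECIFIED_PROFILES: dict[str, tuple[float, float, float]] = {
    # Firmicutes
    "Lactobacillus": (0.1439, 0.040, 0.040),
    "Clostridium sensu stricto 1": (0.1341, 0.1749, 0.025),
    "Turicibacter": (0.055, 0.065, 0.010),
    "Romboutsia": (0.050, 0.060, 0.010),
    "Terrisporobacter": (0.045, 0.050, 0.025),
    "Streptococcus": (0.070, 0.045, 0.045),
    "Christensenellaceae R-7 group": (0.025, 0.015, 0.040),
    "Ruminococcus": (0.030, 0.015, 0.040),
    "Megasphaera": (0.008, 0.004, 0.010),
    "Dialister": (0.010, 0.006, 0.020),
    "Phascolarctobacterium": (0.008, 0.005, 0.025),
    "Sarcina": (0.015, 0.020, 0.004),
    "Mitsuokella": (0.008, 0.004, 0.010),
    "Oscillibacter": (0.008, 0.006, 0.018),
    "Subdoligranulum": (0.010, 0.006, 0.020),
    # butyrate producers, elevated in component 3 in descending order
    "Faecalibacterium": (0.006, 0.003, 0.035),
    "Butyricicoccus": (0.005, 0.0025, 0.022),
    "Eubacterium hallii group": (0.004, 0.002, 0.018),
    "Blautia": (0.005, 0.003, 0.012),
    "Anaerostipes": (0.003, 0.0015, 0.008),
    # producer genera without a planted butyrate link
    "Coprococcus": (0.004, 0.004, 0.004),
    "Oscillospira": (0.003, 0.003, 0.003),
    "Roseburia": (0.004, 0.004, 0.004),
    # Bacteroidetes
    "Bacteroides": (0.045, 0.022, 0.1817),
    "Prevotella": (0.035, 0.014, 0.065),
    "Prevotellaceae NK3B31 group": (0.045, 0.025, 0.045),
    "Alloprevotella": (0.012, 0.008, 0.020),
    "Parabacteroides": (0.008, 0.006, 0.008),
    "Butyricimonas": (0.003, 0.002, 0.014),
    # Actinobacteria
    "Bifidobacterium": (0.010, 0.1178, 0.008),
    "Olsenella": (0.003, 0.020, 0.002),
    "Collinsella": (0.003, 0.018, 0.002),
    # Spirochaetes
    "Treponema": (0.042, 0.022, 0.011),
    # Proteobacteria
    "Succinivibrio": (0.005, 0.024, 0.008),
    "Desulfovibrio": (0.003, 0.013, 0.004),
    "Campylobacter": (0.003, 0.013, 0.004),
    # Acidobacteria
    "Acidobacteria Gp6": (0.002, 0.017, 0.0001),
    # other phyla
    "Fibrobacter": (0.004, 0.002, 0.006),
    "Akkermansia": (0.003, 0.002, 0.006),
}

PRODUCER_GENERA = [
    "Faecalibacterium", "Butyricicoccus", "Eubacterium hallii group",
    "Butyricimonas", "Blautia", "Anaerostipes", "Coprococcus",
    "Oscillospira", "Roseburia",
]

#: genera scaled together by the shared co-occurrence latent factor
COOCCURRING_TRIO = ["Clostridium sensu stricto 1", "Turicibacter", "Romboutsia"]

#: butyrate mg/g gained per unit relative abundance of each planted producer
DEFAULT_PRODUCER_SLOPES = {
    "Faecalibacterium": 50.0,
    "Butyricicoccus": 14.0,
    "Eubacterium hallii group": 10.0,
    "Butyricimonas": 7.0,
    "Blautia": 4.0,
    "Anaerostipes": 2.0,
}


def _component_profiles() -> pd.DataFrame:
    """Taxa x 3 mean-profile matrix; each column sums to exactly 1.

    The unclassified bin (ambiguous genus assignments are common in 16S
    genus tables) takes the mass not claimed by named genera."""
    taxa = list(_SPECIFIED_PROFILES) + ["unclassified"]
    mat = np.zeros((len(taxa), 3))
    for i, g in enumerate(_SPECIFIED_PROFILES):
        mat[i] = _SPECIFIED_PROFILES[g]
    remainder = 1.0 - mat[:-1].sum(axis=0)
    if (remainder <= 0).any():
        raise ValueError("specified component means exceed 1")
    mat[-1] = remainder
    return pd.DataFrame(mat, index=taxa, columns=["comp1", "comp2", "comp3"])


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_samples: int = 105
    k: int = 3
    mixing: tuple = (1 / 3, 1 / 3, 1 / 3)
    concentration: float = 300.0
    depth_range: tuple = (40_000, 100_000)
    intercept: float = 0.6
    producer_slopes: dict = field(default_factory=lambda: dict(DEFAULT_PRODUCER_SLOPES))
    noise_sd: float = 0.35
    coupling_but: float = 0.7464
    coupling_buk: float = 0.4905
    but_log10_mean: float = 8.5
    but_log10_sd: float = 0.6
    buk_log10_mean: float = 7.2
    buk_log10_sd: float = 0.5
    cooccurrence_sigma: float = 0.3
    include_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.k != len(self.mixing):
            raise ValueError("mixing proportions must have length k")
        if abs(sum(self.mixing) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (1 <= self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth_range must satisfy 1 <= low <= high")

    def profiles(self) -> pd.DataFrame:
        base = _component_profiles()
        if self.k == 3:
            return base
        if self.k == 1:
            mixed = base.to_numpy() @ np.array([1 / 3, 1 / 3, 1 / 3])
            return pd.DataFrame({"comp1": mixed}, index=base.index)
        if self.k == 2:
            return base[["comp1", "comp3"]].rename(columns={"comp3": "comp2"})
        raise ValueError("k must be 1, 2 or 3 for the default roster")

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["mixing"] = list(self.mixing)
        doc["depth_range"] = list(self.depth_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError("config file must hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "mixing" in doc:
            doc["mixing"] = tuple(doc["mixing"])
        if "depth_range" in doc:
            doc["depth_range"] = tuple(doc["depth_range"])
        return cls(**doc)


@dataclass
class SyntheticTruth:
    """Ground truth recorded next to a generated cohort."""

    component_labels: np.ndarray  # 1..K
    dirichlet_alpha: pd.DataFrame  # taxa x K
    depths: np.ndarray
    phenotype_coefficients: dict
    gene_copy_couplings: dict
    seed: int


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study conditions: 105 samples, 3 components."""
    return CohortConfig(seed=seed, **overrides)


def _noisy_monotone(rng, anchor: np.ndarray, target_rho: float, mean: float, sd: float) -> np.ndarray:
    """Gaussian-noised monotone transform of ``anchor`` whose realized
    Spearman correlation with it approaches ``target_rho``.

    Uses the normal-score construction: z = Phi^-1 of the anchor's rank
    quantile; the Pearson coefficient on normal scores that yields
    Spearman rho is r = 2 sin(pi rho / 6)."""
    n = len(anchor)
    z = norm.ppf((rankdata(anchor) - 0.5) / n)
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    eps = rng.standard_normal(n)
    return mean + sd * (r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[AbundanceTable, PhenotypeTable, SyntheticTruth]:
    """Draw one cohort: counts table, phenotypes and ground truth."""
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    profiles = config.profiles()
    taxa = list(profiles.index)
    k = profiles.shape[1]
    n = config.n_samples

    labels = rng.choice(k, size=n, p=np.asarray(config.mixing)) + 1
    lo, hi = config.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)

    trio_idx = [taxa.index(g) for g in COOCCURRING_TRIO if g in taxa]
    alpha_base = config.concentration * profiles.to_numpy()  # taxa x k
    counts = np.zeros((n, len(taxa)), dtype=float)
    for i in range(n):
        alpha = alpha_base[:, labels[i] - 1].copy()
        if config.cooccurrence_sigma > 0 and trio_idx:
            g = rng.lognormal(0.0, config.cooccurrence_sigma)
            alpha[trio_idx] *= g
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], p)
    rel = counts / depths[:, None]

    slopes = {g: s for g, s in config.producer_slopes.items() if g in taxa}
    signal = sum(
        s * rel[:, taxa.index(g)] for g, s in slopes.items()
    ) if slopes else np.zeros(n)
    butyrate = np.maximum(
        0.0, config.intercept + signal + rng.normal(0.0, config.noise_sd, size=n)
    )
    but = _noisy_monotone(
        rng, butyrate, config.coupling_but, config.but_log10_mean, config.but_log10_sd
    )
    buk = _noisy_monotone(
        rng, butyrate, config.coupling_buk, config.buk_log10_mean, config.buk_log10_sd
    )

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxa), COUNTS
    )
    phen = {BUTYRATE: butyrate, BUK: buk, BUT: but}
    if config.include_covariates:
        phen.update(
            {
                "water_pct": rng.normal(72.0, 3.0, size=n),
                "pH": rng.normal(7.4, 0.35, size=n),
                "organic_matter_g_per_kg": rng.normal(307.0, 40.0, size=n),
                "total_nitrogen_g_per_kg": rng.normal(43.0, 5.0, size=n),
                "total_phosphorus_g_per_kg": rng.normal(30.0, 4.0, size=n),
            }
        )
    phenotype = PhenotypeTable(pd.DataFrame(phen, index=sample_ids))
    truth = SyntheticTruth(
        component_labels=labels,
        dirichlet_alpha=pd.DataFrame(
            alpha_base, index=taxa, columns=list(profiles.columns)
        ),
        depths=depths,
        phenotype_coefficients={
            "intercept": config.intercept,
            "slopes": dict(slopes),
            "noise_sd": config.noise_sd,
        },
        gene_copy_couplings={"but": config.coupling_but, "buk": config.coupling_buk},
        seed=config.seed,
    )
    return table, phenotype, truth


def null_cohort(
    config: CohortConfig | None = None,
) -> tuple[AbundanceTable, PhenotypeTable, SyntheticTruth]:
    """Structure-free negative control: one component, taxa-independent
    phenotype.  Gene copies remain coupled to butyrate, but butyrate is
    pure noise around the intercept."""
    config = config or default_config()
    flat = CohortConfig(
        **{
            **{f: getattr(config, f) for f in config.__dataclass_fields__},
            "k": 1,
            "mixing": (1.0,),
            "producer_slopes": {},
            "cooccurrence_sigma": 0.0,
        }
    )
    return generate_cohort(flat)


def write_truth(truth: SyntheticTruth, tsv_path: str | Path, json_path: str | Path) -> None:
    import json

    pd.DataFrame(
        {"component": truth.component_labels, "depth": truth.depths},
        index=pd.Index(
            [f"S{i + 1:03d}" for i in range(len(truth.component_labels))],
            name="sample_id",
        ),
    ).to_csv(tsv_path, sep="\t")
    doc = {
        "phenotype_coefficients": truth.phenotype_coefficients,
        "gene_copy_couplings": truth.gene_copy_couplings,
        "seed": int(truth.seed),
        "dirichlet_alpha": {
            c: truth.dirichlet_alpha[c].round(10).to_dict()
            for c in truth.dirichlet_alpha.columns
        },
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1)
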