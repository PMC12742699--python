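"""Synthetic data with known ground truth for every pipeline stage.

The specimen generator emulates the sampling structure of the real survey:
two sibling species sampled as nest series (40 and 46 nests, up to three
minor workers each), cephalic size CS drawn from a truncated normal matching
the observed size distribution, and each ratio index following a linear
allometric law k*CS + d (the published correction lines by default) plus a
nest-level random effect and residual measurement noise. Species differ by
small opposite shifts of the intercepts, with the sign pattern of the real
between-species differences. Raw characters are back-computed from CS and the
drawn indices, so recomputing indices from the emitted table reproduces the
latent values exactly.

The site generator emulates the co-occurrence survey: a fixed number of sites
per focal class, each model species present independently with a
class-conditional probability (the empirical survey proportions by default).

One seed drives independent named substreams, so e.g. changing the number of
sites leaves the specimen draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import biogeo
from .allometry import printed_parameters
from .morphodata import CHARACTERS, INDICES

#: Direction of the species-2 minus species-1 index difference (observed
#: pattern of the real species pair: relatively longer legs/mesosoma and deeper
#: grooves in one species, longer antennal and petiolar proportions in the
#: other).
OFFSET_SIGNS = {
    "CL/CW": +1, "dAN/CS": -1, "EL/CS": -1, "HTL/CS": +1, "MGr/CS": +1,
    "ML/CS": +1, "MW/CS": +1, "NOL/CS": +1, "PeSH/CS": -1, "PeW/CS": -1,
    "PreOc/CL": +1, "PrGr/CS": +1, "SL/CS": +1,
}

#: Default class-conditional model-presence probabilities: the empirical
#: proportions of the published survey (rows: focal class, cols: model).
DEFAULT_PRESENCE_PROBS = {
    "truncata": {"Do_quadripunctatus": 32 / 33, "Cr_scutellaris": 15 / 33,
                 "Cr_schmidti": 5 / 33, "Cr_ionia_sl": 2 / 33},
    "imitans_truncata_like": {"Do_quadripunctatus": 9 / 9, "Cr_scutellaris": 1 / 9,
                              "Cr_schmidti": 8 / 9, "Cr_ionia_sl": 2 / 9},
    "imitans_red_headed": {"Do_quadripunctatus": 0 / 8, "Cr_scutellaris": 8 / 8,
                           "Cr_schmidti": 0 / 8, "Cr_ionia_sl": 0 / 8},
    "imitans_blackish": {"Do_quadripunctatus": 1 / 10, "Cr_scutellaris": 0 / 10,
                         "Cr_schmidti": 1 / 10, "Cr_ionia_sl": 10 / 10},
}


@dataclass
class SynthConfig:
    """Study-design parameters of the generators.

    ``species_offset``, ``sigma_nest`` and ``sigma_res`` are fractions of each
    index's reference-size value k*0.9 + d. The +-6% default offset is the
    smallest scale at which the nest-centroid clusters separate clearly enough
    in raw character space (mean silhouette comfortably above 0.5 at every
    seed) for the unsupervised stage to recover them; +-2% reproduces the
    marginal regime of the real data, where k-means partitioning collapses the
    samples into a single group.
    """

    nests: tuple = (40, 46)
    workers_per_nest: int = 3
    species_names: tuple = ("truncata", "imitans")
    cs_mean_mm: float = 0.89
    cs_sd_mm: float = 0.05
    cs_range_mm: tuple = (0.70, 1.06)
    species_offset: float = 0.06
    offset_signs: dict = field(default_factory=lambda: dict(OFFSET_SIGNS))
    sigma_nest: float = 0.01
    sigma_res: float = 0.02
    lines: dict | None = None  # index -> (k, d); printed values if None
    latitude_ranges: dict = field(default_factory=lambda: {
        "truncata": (38.0, 48.0), "imitans": (34.0, 42.0)})
    site_class_counts: dict = field(default_factory=lambda: {
        "truncata": 33, "imitans_truncata_like": 9,
        "imitans_red_headed": 8, "imitans_blackish": 10})
    presence_probs: dict = field(default_factory=lambda: {
        c: dict(p) for c, p in DEFAULT_PRESENCE_PROBS.items()})
    seed: int = 0

    def __post_init__(self):
        if self.sigma_nest < 0 or self.sigma_res < 0:
            raise ValueError("noise standard deviations must be >= 0")
        lo, hi = self.cs_range_mm
        if not lo < self.cs_mean_mm < hi:
            raise ValueError("CS truncation bounds must bracket the mean")
        for c, probs in self.presence_probs.items():
            for m, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"presence probability {p} for ({c}, {m})")

    def resolved_lines(self) -> dict:
        if self.lines is not None:
            return dict(self.lines)
        return {name: (ln.k, ln.d) for name, ln in printed_parameters().lines.items()}


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # named substreams off one seed: 0=CS, 1=nest effects, 2=residuals,
    # 3=latitudes, 4=sites
    return np.random.default_rng([int(config.seed) % (2 ** 31), stream])


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def bayes_error_worker(config: SynthConfig) -> float:
    """Optimal single-worker misclassification rate under the generator.

    Conditional on CS (observable from CL and CW), the index vector is
    Gaussian with species-dependent mean gap 2*delta per index and diagonal
    covariance sigma_nest^2 + sigma_res^2, so the Bayes rate for equal priors
    is Phi(-D/2) with D the Mahalanobis separation.
    """
    lines = config.resolved_lines()
    d2 = 0.0
    for name, (k, d) in lines.items():
        ref = k * 0.9 + d
        gap = 2.0 * config.species_offset * abs(ref)
        var = (config.sigma_nest ** 2 + config.sigma_res ** 2) * ref ** 2
        if var > 0:
            d2 += gap ** 2 / var
    if d2 == 0:
        return 0.5
    return float(stats.norm.cdf(-np.sqrt(d2) / 2.0))


def generate_specimens(config: SynthConfig | None = None):
    """Draw a specimen table plus the latent truth behind it.

    Returns ``(records, truth)``: ``records`` follows the canonical
    measurement schema (IDs, labels, locality, 14 characters in micrometres);
    ``truth`` holds the drawn index values, per-species lines, per-nest
    effects, the species of every nest, and the closed-form worker-level
    Bayes error.
    """
    config = config or SynthConfig()
    lines = config.resolved_lines()
    index_names = [n for n in INDICES if n in lines]
    if set(index_names) != set(INDICES):
        raise ValueError("generator needs a line for each of the 13 indices")
    k = np.array([lines[n][0] for n in INDICES])
    d = np.array([lines[n][1] for n in INDICES])
    ref = k * 0.9 + d
    signs = np.array([config.offset_signs.get(n, 1.0) for n in INDICES])
    delta = config.species_offset * np.abs(ref) * signs

    rng_cs, rng_nest, rng_res, rng_lat = (_rng(config, s) for s in range(4))
    rows, truth_rows = [], []
    nest_species, nest_effects = {}, {}
    for sp_idx, (sp_name, n_nests) in enumerate(zip(config.species_names,
                                                    config.nests)):
        d_sp = d + (delta if sp_idx == 1 else -delta)
        lat_lo, lat_hi = config.latitude_ranges.get(sp_name, (np.nan, np.nan))
        for nest_i in range(n_nests):
            nest_id = f"{sp_name}_N{nest_i + 1:03d}"
            u = rng_nest.normal(0.0, config.sigma_nest * np.abs(ref))
            nest_species[nest_id] = sp_name
            nest_effects[nest_id] = u
            lat = float(rng_lat.uniform(lat_lo, lat_hi)) if np.isfinite(lat_lo) else np.nan
            for w in range(config.workers_per_nest):
                cs_mm = float(_truncnorm(rng_cs, config.cs_mean_mm,
                                         config.cs_sd_mm, *config.cs_range_mm,
                                         size=1)[0])
                eps = rng_res.normal(0.0, config.sigma_res * np.abs(ref))
                y = k * cs_mm + d_sp + u + eps
                idx = dict(zip(INDICES, y))
                cs_um = cs_mm * 1000.0
                r = idx["CL/CW"]
                chars = {"CL": 2.0 * cs_um * r / (1.0 + r),
                         "CW": 2.0 * cs_um / (1.0 + r)}
                for name in INDICES:
                    if name == "CL/CW":
                        continue
                    num, den = name.split("/")
                    chars[num] = idx[name] * (chars["CL"] if den == "CL" else cs_um)
                if any(chars[c] < 0 for c in CHARACTERS):
                    bad = min(chars, key=chars.get)
                    raise ValueError(
                        f"configuration produced a negative length for {bad}; "
                        "reduce noise or offsets"
                    )
                specimen_id = f"{nest_id}_w{w + 1}"
                rows.append({"specimen_id": specimen_id, "nest_id": nest_id,
                             "species": sp_name,
                             "color_morph": "none", "latitude": lat, **chars})
                truth_rows.append({"specimen_id": specimen_id, "CS": cs_um,
                                   **idx})
    records = pd.DataFrame(rows)
    records["complete"] = True
    truth = {
        "indices": pd.DataFrame(truth_rows).set_index("specimen_id"),
        "nest_species": nest_species,
        "nest_effects": nest_effects,
        "species_lines": {
            sp: {n: (lines[n][0],
                     lines[n][1] + (1 if i == 1 else -1) * dd)
                 for n, dd in zip(INDICES, delta)}
            for i, sp in enumerate(config.species_names)
        },
        "bayes_error_worker": bayes_error_worker(config),
        "config": config,
    }
    return records, truth


def generate_sites(config: SynthConfig | None = None):
    """Draw a per-site presence/absence table plus its latent truth."""
    config = config or SynthConfig()
    rng = _rng(config, 4)
    rows = []
    for cls, n_sites in config.site_class_counts.items():
        probs = config.presence_probs[cls]
        for i in range(int(n_sites)):
            row = {"site_id": f"{cls}_{i + 1:02d}", "colobopsis_class": cls}
            for model in biogeo.MODELS:
                row[model] = int(rng.random() < probs.get(model, 0.0))
            rows.append(row)
    sites = pd.DataFrame(rows)
    truth = {"presence_probs": {c: dict(p) for c, p in config.presence_probs.items()},
             "config": config}
    return sites, truth
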