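"""Synthetic hot-spring outflow transects with known fringe positions.

The generator emulates the statistical structure the analysis assumes:
each transect starts at a hot, reduced, CO2-charged source and relaxes
exponentially toward distal/atmospheric values downstream — temperature,
DIC, sulfide, and conductivity decay while pH, dissolved oxygen, DOC,
ammonia, and nitrate rise.  Microbial counts come from Gaussian pH ×
temperature niches per taxon, with phototrophs suppressed outright above
the pH-dependent temperature limit for photosynthesis (∼73 °C at
circumneutral-to-basic pH, ∼56 °C below pH 4).  Counts are multinomial
draws conditioned on lognormal library sizes, so depth normalization is a
non-trivial step downstream.

Ground truth records expected relative abundances, guild labels, and the
first downstream site of each transect where expected phototroph
abundance exceeds 1% — the simulated photosynthetic fringe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ASVTable,
    Dataset,
    GeochemTable,
    SampleMetadata,
    TaxonomyTable,
)

GEOCHEM_UNITS = {
    "temperature": "degC",
    "pH": "",
    "conductivity": "uS/cm",
    "DIC": "mg C/L",
    "DOC": "mg C/L",
    "DO": "ppm",
    "sulfide": "ppb",
    "ammonia": "ppm",
    "nitrate": "umolal",
}

PHOTOTROPH = "phototroph"
CHEMOTROPH = "chemotroph"


class ParameterError(ValueError):
    pass


class DegenerateSampleError(ValueError):
    pass


@dataclass
class TransectParams:
    """One outflow: source and distal values plus relaxation rates.

    Every variable follows ``end + (src − end)·exp(−κ·d)`` with additive
    Gaussian noise; negative draws are clipped to 0 (pH instead clipped
    into [0, 14]).
    """

    distances: Sequence[float] = (0.0, 4.0, 10.0, 20.0)   # m
    T_src: float = 90.0
    T_amb: float = 25.0
    pH_src: float = 7.0
    pH_end: float | None = None          # default: pH_src + 1.2
    conductivity_src: float = 2000.0
    conductivity_end: float | None = None  # default: 0.8·src
    DIC_src: float = 30.0
    DIC_end: float | None = None         # default: 0.25·src
    sulfide_src: float = 300.0
    sulfide_end: float = 5.0
    DOC_src: float = 0.2
    DOC_end: float = 1.2
    DO_src: float = 0.3
    DO_end: float = 6.0
    ammonia_src: float = 0.05
    ammonia_end: float = 0.8
    nitrate_src: float = 0.05
    nitrate_end: float = 0.5
    kappa: dict = field(default_factory=lambda: {
        "temperature": 0.08, "pH": 0.10, "conductivity": 0.05,
        "DIC": 0.08, "DOC": 0.10, "DO": 0.10, "sulfide": 0.12,
        "ammonia": 0.10, "nitrate": 0.10,
    })
    noise_sd: dict = field(default_factory=lambda: {
        "temperature": 1.5, "pH": 0.08, "conductivity": 40.0,
        "DIC": 0.8, "DOC": 0.05, "DO": 0.15, "sulfide": 10.0,
        "ammonia": 0.03, "nitrate": 0.02,
    })

    def __post_init__(self) -> None:
        if len(self.distances) < 2:
            raise ParameterError("a transect needs at least 2 sites")
        if self.T_src <= self.T_amb:
            raise ParameterError("T_src must exceed T_amb")
        if any(k < 0 for k in self.kappa.values()):
            raise ParameterError("decay rates must be ≥ 0")
        if any(s < 0 for s in self.noise_sd.values()):
            raise ParameterError("noise SDs must be ≥ 0")
        if self.pH_end is None:
            self.pH_end = min(self.pH_src + 1.2, 14.0)
        if self.conductivity_end is None:
            self.conductivity_end = 0.8 * self.conductivity_src
        if self.DIC_end is None:
            self.DIC_end = 0.25 * self.DIC_src

    def endpoints(self) -> dict[str, tuple[float, float]]:
        """(source, distal) value per geochemical variable."""
        return {
            "temperature": (self.T_src, self.T_amb),
            "pH": (self.pH_src, self.pH_end),
            "conductivity": (self.conductivity_src, self.conductivity_end),
            "DIC": (self.DIC_src, self.DIC_end),
            "DOC": (self.DOC_src, self.DOC_end),
            "DO": (self.DO_src, self.DO_end),
            "sulfide": (self.sulfide_src, self.sulfide_end),
            "ammonia": (self.ammonia_src, self.ammonia_end),
            "nitrate": (self.nitrate_src, self.nitrate_end),
        }


def simulate_geochem_transect(
    params: TransectParams,
    seed: int | np.random.Generator,
    spring_id: str = "SP",
) -> tuple[GeochemTable, SampleMetadata]:
    """Geochemistry and metadata for the sites of one outflow transect."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.asarray(params.distances, dtype=float)
    rows = {}
    for var, (src, end) in params.endpoints().items():
        decay = np.exp(-params.kappa[var] * d)
        values = end + (src - end) * decay
        sd = params.noise_sd[var]
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=len(d))
        if var == "pH":
            values = np.clip(values, 0.0, 14.0)
        else:
            values = np.clip(values, 0.0, None)
        rows[var] = values

    sample_ids = [f"{spring_id}-{i + 1}" for i in range(len(d))]
    geochem = GeochemTable(
        pd.DataFrame(rows, index=sample_ids), dict(GEOCHEM_UNITS)
    )
    meta = SampleMetadata(pd.DataFrame({
        "spring_id": spring_id,
        "outflow_index": np.arange(1, len(d) + 1),
        "distance": d,
        "fringe_label": "unknown",
    }, index=sample_ids))
    return geochem, meta


# ---------------------------------------------------------------------------
# niches and counts

@dataclass
class NicheParams:
    """Gaussian pH × temperature niches for a synthetic community.

    Phototroph intensity is forced to zero wherever temperature exceeds the
    photosynthesis limit for the site's pH regime (``T_lim_basic`` at or
    above ``pH_cut``, ``T_lim_acid`` below it).  ``sulfide_threshold``
    optionally suppresses phototrophs at high sulfide; it is off by default
    because sulfide shows no community-level effect in these systems.
    """

    guilds: np.ndarray                 # per-taxon guild label
    pH_opt: np.ndarray
    pH_tol: np.ndarray
    T_opt: np.ndarray
    T_tol: np.ndarray
    peak: np.ndarray
    T_lim_basic: float = 73.0
    T_lim_acid: float = 56.0
    pH_cut: float = 4.0
    sulfide_threshold: float | None = None     # ppb; None disables
    lib_log_mean: float = float(np.log(2.0e4))
    lib_log_sd: float = 0.4

    def __post_init__(self) -> None:
        n = len(self.guilds)
        for name in ("pH_opt", "pH_tol", "T_opt", "T_tol", "peak"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ParameterError(f"{name} length {len(arr)} != n_taxa {n}")
        if (self.pH_tol <= 0).any() or (self.T_tol <= 0).any():
            raise ParameterError("niche tolerances must be > 0")
        if (self.peak <= 0).any():
            raise ParameterError("peak intensities must be > 0")
        if not 0 < self.pH_cut < 14:
            raise ParameterError("pH cut must lie in (0, 14)")

    @property
    def n_taxa(self) -> int:
        return len(self.guilds)

    @classmethod
    def default_community(cls, n_phototrophs: int = 24,
                          n_chemotrophs: int = 36) -> "NicheParams":
        """A fixed 60-taxon community spanning the study's pH/T ranges.

        Optima lie on deterministic grids: phototrophs at 35–70 °C (below
        both photosynthesis limits) across pH 2.5–9; chemotrophs at
        30–95 °C across pH 1.5–9.5.  Peak intensities cycle through a small
        fixed range so no taxon dominates by construction.
        """
        ph_p = np.linspace(2.5, 9.0, n_phototrophs)
        t_p = 35.0 + 35.0 * ((np.arange(n_phototrophs) * 7) % n_phototrophs) / max(n_phototrophs - 1, 1)
        ph_c = np.linspace(1.5, 9.5, n_chemotrophs)
        t_c = 30.0 + 65.0 * ((np.arange(n_chemotrophs) * 11) % n_chemotrophs) / max(n_chemotrophs - 1, 1)
        n = n_phototrophs + n_chemotrophs
        peaks = 0.6 + 0.8 * ((np.arange(n) * 3) % 5) / 4.0
        return cls(
            guilds=np.array([PHOTOTROPH] * n_phototrophs + [CHEMOTROPH] * n_chemotrophs),
            pH_opt=np.concatenate([ph_p, ph_c]),
            pH_tol=np.full(n, 1.1),
            T_opt=np.concatenate([t_p, t_c]),
            T_tol=np.full(n, 12.0),
            peak=peaks,
        )


@dataclass
class GroundTruth:
    """What the generator actually put in each sample."""

    expected_abundance: pd.DataFrame          # taxa × samples, columns sum to 1
    guilds: pd.Series                         # taxon -> guild
    fringe_index: dict[str, int | None]       # spring -> outflow_index of fringe
    photosynthetic: pd.Series                 # sample -> bool (expected phototrophs > 1%)

    def phototroph_fraction(self) -> pd.Series:
        mask = (self.guilds == PHOTOTROPH).to_numpy()
        return self.expected_abundance.iloc[mask].sum(axis=0)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "spring_id": list(self.fringe_index),
            "fringe_index": [v if v is not None else -1
                             for v in self.fringe_index.values()],
        }).to_csv(outdir / "truth_fringe.tsv", sep="\t", index=False)
        pd.DataFrame({"guild": self.guilds}).to_csv(
            outdir / "truth_guilds.tsv", sep="\t", index_label="asv_id")
        self.expected_abundance.to_csv(
            outdir / "truth_expected_abundance.tsv", sep="\t",
            index_label="asv_id", float_format="%.10g")


def expected_relative_abundance(
    geochem: GeochemTable, niche: NicheParams
) -> pd.DataFrame:
    """Niche intensities normalized per sample, with phototroph suppression."""
    pH = geochem.values["pH"].to_numpy()
    T = geochem.values["temperature"].to_numpy()
    lam = (
        niche.peak[:, None]
        * np.exp(-((pH[None, :] - niche.pH_opt[:, None]) ** 2)
                 / (2 * niche.pH_tol[:, None] ** 2))
        * np.exp(-((T[None, :] - niche.T_opt[:, None]) ** 2)
                 / (2 * niche.T_tol[:, None] ** 2))
    )
    limit = np.where(pH >= niche.pH_cut, niche.T_lim_basic, niche.T_lim_acid)
    photo = (np.asarray(niche.guilds) == PHOTOTROPH)[:, None]
    lam[photo & (T[None, :] > limit[None, :])] = 0.0
    if niche.sulfide_threshold is not None and "sulfide" in geochem.variables:
        sulf = geochem.values["sulfide"].to_numpy()
        lam[photo & (sulf[None, :] > niche.sulfide_threshold)] = 0.0

    totals = lam.sum(axis=0)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        bad = [geochem.sample_ids[i] for i in dead]
        raise DegenerateSampleError(f"all niche intensities zero at: {bad}")
    taxa = [f"ASV{i + 1:04d}" for i in range(niche.n_taxa)]
    return pd.DataFrame(lam / totals, index=taxa, columns=geochem.sample_ids)


def simulate_counts(
    geochem: GeochemTable,
    niche: NicheParams,
    seed: int | np.random.Generator,
    metadata: SampleMetadata | None = None,
    fringe_fraction: float = 0.01,
) -> tuple[ASVTable, GroundTruth]:
    """Multinomial ASV counts from niche-model expected abundances.

    Library sizes are lognormal; the realized count column of sample *s*
    sums to its drawn library size exactly.  The truth fringe of each
    transect (when ``metadata`` is given) is the first downstream site
    whose expected phototroph fraction exceeds ``fringe_fraction``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = expected_relative_abundance(geochem, niche)
    libs = np.maximum(
        1, np.round(rng.lognormal(niche.lib_log_mean, niche.lib_log_sd,
                                  size=p.shape[1])).astype(np.int64)
    )
    counts = np.column_stack([
        rng.multinomial(libs[j], p.iloc[:, j].to_numpy())
        for j in range(p.shape[1])
    ])
    table = ASVTable(pd.DataFrame(counts, index=p.index, columns=p.columns))

    guilds = pd.Series(np.asarray(niche.guilds), index=p.index, name="guild")
    photo_frac = p.iloc[(guilds == PHOTOTROPH).to_numpy()].sum(axis=0)
    photosynthetic = photo_frac > fringe_fraction

    fringe: dict[str, int | None] = {}
    if metadata is not None:
        for spring, sub in metadata.transects():
            fringe[spring] = None
            for sid, row in sub.iterrows():
                if photosynthetic.get(sid, False):
                    fringe[spring] = int(row["outflow_index"])
                    break
    truth = GroundTruth(p, guilds, fringe, photosynthetic)
    return table, truth


# ---------------------------------------------------------------------------
# full study

@dataclass
class StudyParams:
    """Defaults mirror the field design: 12 transects of 4 sites spanning
    acidic (4), circumneutral (3), and basic (5) sources."""

    pH_sources: Sequence[float] = (
        2.0, 2.5, 3.0, 3.5,            # acidic
        4.5, 5.5, 6.5,                 # circumneutral
        7.2, 7.6, 8.0, 8.5, 9.0,       # basic
    )
    n_sites: int = 4
    niche: NicheParams | None = None
    fringe_fraction: float = 0.01

    def transect(self, i: int) -> TransectParams:
        """Per-spring parameters; sources covary with pH the way YNP springs
        do: basic springs are DIC-rich, acidic springs carry more DOC and
        ammonia and higher conductivity."""
        pH = float(self.pH_sources[i])
        d = tuple(np.linspace(0.0, 20.0, self.n_sites))
        return TransectParams(
            distances=d,
            T_src=85.0 + 10.0 * (i % 3) / 2.0,   # 85–95 °C
            pH_src=pH,
            DIC_src=max(0.5, 8.0 * (pH - 1.5)),
            DOC_end=max(0.3, 2.2 - 0.18 * pH),
            ammonia_end=max(0.1, 2.4 - 0.22 * pH),
            conductivity_src=3200.0 - 220.0 * pH,
            sulfide_src=150.0 + 400.0 * np.exp(-0.5 * (pH - 3.0) ** 2),
        )


def _synthetic_taxonomy(guilds: pd.Series) -> TaxonomyTable:
    """Guild encoded at class rank so class aggregation exposes it."""
    lineages = {}
    for asv, guild in guilds.items():
        cls_name = "Phototrophia" if guild == PHOTOTROPH else "Chemotrophia"
        lineages[asv] = (
            f"d__Bacteria;p__Simulobacteria;c__{cls_name};"
            f"o__{cls_name}les;f__{cls_name}ceae;g__{asv};s__"
        )
    return TaxonomyTable.from_lineage_strings(lineages)


def simulate_study(
    params: StudyParams | None = None, seed: int = 0
) -> tuple[Dataset, GroundTruth]:
    """Concatenated multi-spring study with ground truth, fully seeded."""
    params = params or StudyParams()
    niche = params.niche or NicheParams.default_community()
    ss = np.random.SeedSequence(seed)
    geo_rng, count_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    geos, metas = [], []
    for i in range(len(params.pH_sources)):
        spring = f"SP{i + 1:02d}"
        g, m = simulate_geochem_transect(params.transect(i), geo_rng, spring)
        geos.append(g)
        metas.append(m)
    geochem = GeochemTable(pd.concat([g.values for g in geos]),
                           dict(GEOCHEM_UNITS))
    metadata = SampleMetadata(pd.concat([m.table for m in metas]))

    counts, truth = simulate_counts(
        geochem, niche, count_rng, metadata=metadata,
        fringe_fraction=params.fringe_fraction,
    )

    # label samples relative to the per-transect truth fringe
    labels = {}
    for spring, sub in metadata.transects():
        fr = truth.fringe_index.get(spring)
        for sid, row in sub.iterrows():
            if fr is None:
                labels[sid] = "unknown"
            elif row["outflow_index"] < fr:
                labels[sid] = "above"
            elif row["outflow_index"] == fr:
                labels[sid] = "at"
            else:
                labels[sid] = "below"
    metadata.table["fringe_label"] = pd.Series(labels)

    taxonomy = _synthetic_taxonomy(truth.guilds)
    dataset = Dataset(geochem, counts, taxonomy, metadata)
    return dataset, truth
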