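"""Synthetic FT-Raman and FTIR spectral blocks with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: six Mucoromycota strains (Ar, Mc1, Mc2, Mr, Rs, Uv) cultivated at
three phosphate levels (Pi0.5, Pi1, Pi4) with and without calcium (Ca0/Ca1),
two biological replicates, three technical replicates — 72 biological
samples and 216 spectra per block.  Each spectrum is a multiplicative gain
times a linear mixture of component band profiles (Lorentzian sums built
from the band catalog) plus a polynomial baseline drift, an optional
broad heating-emission baseline for the strain × condition cells known to
heat under the laser, and white noise.

Component concentrations are design-driven: per-strain lipid and phosphorus
levels span the published composition ranges and respond to the phosphate
level; chitin is overproduced under low phosphate and suppressed without
calcium (calcium activates chitin synthase); carotenoids in the pigmented
strains rise sharply under low phosphate without calcium (an order of
magnitude for Mc2); carotenoid bands are resonance-enhanced and exist only
in the Raman block.  Dry-weight fractions respect mass closure: the
structural pool (cell wall carbohydrates + protein) fills whatever dry
weight lipids, polyphosphates and pigments leave, which induces the
lipid-versus-carbohydrate anti-correlation seen in real fungal biomass.
Both blocks share the same concentration draws per
biological sample, and the returned chemistry table carries the true values
in the units of the reference analyses (% dry weight, µg/g dry weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError
from .spectra_io import (
    CA_LEVELS,
    DEFAULT_SPACING,
    PI_LEVELS,
    STRAINS,
    SpectraSet,
)

COMPONENTS = ("lipid", "chitin", "chitosan_glucan", "protein", "polyphosphate", "carotenoid")

RAMAN_RANGE = (3785.0, 50.0)
FTIR_RANGE = (4000.0, 400.0)

# ---------------------------------------------------------------------------
# band catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    component: str
    block: str
    center: float  # cm⁻¹
    height: float  # relative, unit concentration
    width: float  # FWHM, cm⁻¹
    assignment: str


@dataclass
class BandCatalog:
    """Catalog of component bands for one spectral block."""

    block: str
    entries: list[Band]

    def for_component(self, component: str) -> list[Band]:
        return [b for b in self.entries if b.component == component]

    def components(self) -> list[str]:
        seen = []
        for b in self.entries:
            if b.component not in seen:
                seen.append(b.component)
        return seen


# Lorentzian FWHM defaults: 16 cm⁻¹ for ordinary condensed-phase bands,
# 10 cm⁻¹ for the resonance-enhanced carotenoid bands, broad for O-H/N-H.
_W = 16.0
_WC = 10.0
_WP = 12.0
_WB = 120.0

_RAMAN_BANDS = [
    # acylglycerol lipids (triglycerides) — C-H stretches are the strongest
    ("lipid", 3008, 0.55, _W, "=C-H str."),
    ("lipid", 2933, 1.00, _W, "-C-H str. (CH3)"),
    ("lipid", 2895, 0.85, _W, "-C-H str. (CH3)"),
    ("lipid", 2855, 0.90, _W, "-C-H str. (CH2)"),
    ("lipid", 1750, 0.50, _W, "C=O str. (ester)"),
    ("lipid", 1660, 0.45, _W, "C=C str."),
    ("lipid", 1445, 0.65, _W, "CH2 and CH3 def."),
    ("lipid", 1305, 0.40, _W, "CH2 def."),
    ("lipid", 1070, 0.30, _W, "C-C str., C-O str."),
    # chitin (glucosamine cell-wall polymer)
    ("chitin", 2933, 0.70, _W, "-C-H str. (CH3)"),
    ("chitin", 2895, 0.60, _W, "-C-H str. (CH3)"),
    ("chitin", 1650, 0.55, _W, "-C=O str. (Amide I)"),
    ("chitin", 1450, 0.50, _W, "CH2 and CH3 def."),
    ("chitin", 1377, 0.45, _W, "CH2, CH, COH def."),
    ("chitin", 1327, 0.40, _W, "CH2, CH, COH def."),
    ("chitin", 1256, 0.30, _W, "C-C, C-O, CH, CH2"),
    ("chitin", 1155, 0.50, _W, "C-N str., C-C str."),
    ("chitin", 1109, 0.35, _W, "C-O-C str."),
    ("chitin", 950, 0.25, _W, "C-C, C-O-C str., COH def."),
    ("chitin", 715, 0.18, _W, "O-C-O str., CH def."),
    # chitosan / glucans / glucuronans
    ("chitosan_glucan", 2933, 0.55, _W, "-C-H str. (CH3)"),
    ("chitosan_glucan", 2855, 0.50, _W, "-C-H str. (CH2, glucan)"),
    ("chitosan_glucan", 1755, 0.25, _W, "-C=O str. (glucuronan)"),
    ("chitosan_glucan", 1595, 0.35, _W, "NH2 def. (chitosan)"),
    ("chitosan_glucan", 1450, 0.45, _W, "CH2 and CH3 def."),
    ("chitosan_glucan", 1377, 0.35, _W, "CH2, CH, COH def."),
    ("chitosan_glucan", 1256, 0.30, _W, "C-C, C-O, CH, CH2"),
    ("chitosan_glucan", 1175, 0.28, _W, "C-O-C str."),
    ("chitosan_glucan", 1100, 0.32, _W, "C-N str., C-C str."),
    ("chitosan_glucan", 900, 0.28, _W, "C-C, C-O-C str."),
    ("chitosan_glucan", 715, 0.20, _W, "O-C-O str., CH def."),
    # proteins
    ("protein", 2935, 0.70, _W, "C-H str."),
    ("protein", 1660, 0.80, _W, "-C=O str. (Amide I)"),
    ("protein", 1615, 0.35, _W, "NH2 def."),
    ("protein", 1605, 0.45, _W, "C=C str. (phenyl ring)"),
    ("protein", 1450, 0.50, _W, "CH2 and CH3 def."),
    ("protein", 1280, 0.40, _W, "C-N-H def. (Amide III)"),
    ("protein", 1005, 0.60, _W, "phenyl ring def."),
    # polyphosphates — weak in Raman
    ("polyphosphate", 1165, 0.35, _WP, "P=O str. (PO2-)"),
    ("polyphosphate", 685, 0.18, _WP, "P-O-P str."),
    # carotenoids — resonance-enhanced, Raman only
    ("carotenoid", 1525, 420.0, _WC, "C=C str. (polyene chain)"),
    ("carotenoid", 1155, 280.0, _WC, "C-C str., CH def."),
    ("carotenoid", 1005, 130.0, _WC, "C-CH3 def."),
]

_FTIR_BANDS = [
    ("lipid", 3010, 0.30, _W, "=C-H str."),
    ("lipid", 2921, 1.00, _W, "-C-H str. (CH3)"),
    ("lipid", 2852, 0.80, _W, "-C-H str. (CH2)"),
    ("lipid", 1743, 0.90, _W, "-C=O str."),
    ("lipid", 1463, 0.40, _W, "-CH2 def."),
    ("lipid", 1160, 0.40, _W, "C-O-C str."),
    ("lipid", 723, 0.15, _W, "-CH2 def."),
    ("chitin", 3270, 0.50, _WB, "N-H str., N-H2 str."),
    ("chitin", 2879, 0.30, _W, "-C-H str. (CH3)"),
    ("chitin", 1650, 0.80, _W, "-C=O str. (Amide I)"),
    ("chitin", 1554, 0.60, _W, "C-N str., NH def. (Amide II)"),
    ("chitin", 1375, 0.35, _W, "-CH3 def."),
    ("chitin", 1305, 0.30, _W, "C-N-H def. (Amide III)"),
    ("chitin", 1070, 0.70, _W, "C-O-C str., COH def."),
    ("chitin", 950, 0.20, _W, "-CH3 def."),
    ("chitosan_glucan", 3300, 0.60, _WB, "O-H str."),
    ("chitosan_glucan", 2879, 0.35, _W, "-C-H str. (CH3)"),
    ("chitosan_glucan", 1730, 0.25, _W, "-C=O str. (glucuronans)"),
    ("chitosan_glucan", 1575, 0.40, _W, "NH2 def. (chitosan)"),
    ("chitosan_glucan", 1375, 0.30, _W, "-CH3 def."),
    ("chitosan_glucan", 1100, 0.80, _W, "C-O-C str."),
    ("chitosan_glucan", 1030, 0.60, _W, "COH def."),
    ("chitosan_glucan", 950, 0.25, _W, "-CH3 def."),
    ("protein", 2960, 0.30, _W, "C-H str."),
    ("protein", 1655, 1.00, _W, "-C=O str. (Amide I)"),
    ("protein", 1545, 0.70, _W, "C-N-H def. (Amide II)"),
    ("protein", 1280, 0.30, _W, "C-N-H def. (Amide III)"),
    # polyphosphates — strong in FTIR
    ("polyphosphate", 1263, 1.60, _WP, "P=O str. (PO2-)"),
    ("polyphosphate", 885, 1.00, _WP, "P-O-P str."),
    # carotenoids: not detectable by FTIR at biomass concentrations
]


def make_band_catalog(block: str) -> BandCatalog:
    """Return the band catalog of one block.

    Carotenoid entries exist only in the Raman catalog (resonance Raman
    effect; at µg/g levels carotenoids are invisible to FTIR), and the Raman
    polyphosphate bands are weak while their FTIR counterparts are strong.
    """
    if block == "raman":
        rows, lohi = _RAMAN_BANDS, RAMAN_RANGE
    elif block == "ftir":
        rows, lohi = _FTIR_BANDS, FTIR_RANGE
    else:
        raise DesignError(f"unknown block {block!r}; expected 'raman' or 'ftir'")
    entries = [Band(c, block, ctr, h, w, a) for c, ctr, h, w, a in rows]
    hi, lo = lohi
    for b in entries:
        assert lo <= b.center <= hi and b.height > 0
    return BandCatalog(block, entries)


@dataclass
class ComponentProfile:
    """Pure-component spectrum at unit concentration on a block grid."""

    component: str
    block: str
    grid: np.ndarray
    pure_spectrum: np.ndarray


def synth_component_spectrum(
    catalog: BandCatalog, component: str, grid: np.ndarray
) -> ComponentProfile:
    """Sum of unit-peak Lorentzians for every band of one component."""
    bands = catalog.for_component(component)
    if not bands:
        raise DesignError(
            f"component {component!r} has no bands in the {catalog.block} catalog"
        )
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    for b in bands:
        hwhm = b.width / 2.0
        y += b.height / (1.0 + ((grid - b.center) / hwhm) ** 2)
    return ComponentProfile(component, catalog.block, grid, y)


# ---------------------------------------------------------------------------
# design effects
# ---------------------------------------------------------------------------

#: Published per-strain total-lipid ranges, % of dry weight.
LIPID_RANGE_PCT = {
    "Ar": (27.0, 49.0),
    "Mc1": (20.0, 49.0),
    "Mc2": (34.0, 52.0),
    "Mr": (19.0, 41.0),
    "Rs": (22.0, 28.0),
    "Uv": (49.0, 83.0),
}

#: Published per-strain total-phosphorus ranges, % of dry weight.
PHOSPHORUS_RANGE_PCT = {
    "Ar": (2.65, 6.24),
    "Mc1": (1.40, 4.91),
    "Mc2": (1.86, 4.50),
    "Mr": (2.28, 5.20),
    "Rs": (2.70, 4.13),
    "Uv": (0.64, 1.37),
}

#: Baseline carotenoid content at the reference condition (Pi1, Ca1), µg/g.
CAROTENOID_BASE_UGG = {"Ar": 200.0, "Mc1": 150.0, "Mc2": 145.0, "Mr": 30.0, "Rs": 25.0, "Uv": 15.0}

#: Condition multipliers for the carotenogenic strains; Mc2 shows the
#: order-of-magnitude surge under low phosphate without calcium.
_CAROT_BOOST = {
    "Mc2": {(0.5, 0): 10.0, (0.5, 1): 3.0, (1.0, 0): 2.5, (1.0, 1): 1.0, (4.0, 0): 1.5, (4.0, 1): 0.8},
    "Mc1": {(0.5, 0): 3.0, (0.5, 1): 1.6, (1.0, 0): 1.5, (1.0, 1): 1.0, (4.0, 0): 1.2, (4.0, 1): 0.9},
    "Ar": {(0.5, 0): 2.5, (0.5, 1): 1.8, (1.0, 0): 1.4, (1.0, 1): 1.0, (4.0, 0): 1.1, (4.0, 1): 0.9},
}

CHITIN_BASE_PCT = {"Ar": 8.0, "Mc1": 12.0, "Mc2": 7.0, "Mr": 9.0, "Rs": 8.0, "Uv": 3.0}


def _heating_flagged(strain: str, pi: float, ca: int) -> bool:
    """Cells measured at reduced laser power because of sample heating.

    Rhizopus stolonifer sporulates under moderate and high phosphate, and a
    couple of Amylomyces rouxii cultures heat as well — ten biological
    samples in total.
    """
    if strain == "Rs" and pi in (1.0, 4.0):
        return True
    if strain == "Ar" and pi == 4.0 and ca == 1:
        return True
    return False


@dataclass
class DesignEffects:
    """Concentration and noise model of the synthetic design.

    Concentration units are mass fractions internally; the chemistry table
    reports % dry weight (lipids, phosphorus) and µg/g (carotenoids).
    """

    lipid_range_pct: dict = field(default_factory=lambda: dict(LIPID_RANGE_PCT))
    phosphorus_range_pct: dict = field(default_factory=lambda: dict(PHOSPHORUS_RANGE_PCT))
    carotenoid_base_ugg: dict = field(default_factory=lambda: dict(CAROTENOID_BASE_UGG))
    carotenoid_boost: dict = field(default_factory=lambda: {k: dict(v) for k, v in _CAROT_BOOST.items()})
    chitin_base_pct: dict = field(default_factory=lambda: dict(CHITIN_BASE_PCT))
    chitin_pi_mult: dict = field(default_factory=lambda: {0.5: 1.5, 1.0: 1.0, 4.0: 0.85})
    chitin_ca0_mult: float = 0.6
    glucan_base_pct: float = 15.0
    glucan_pi_mult: dict = field(default_factory=lambda: {0.5: 1.15, 1.0: 1.0, 4.0: 0.95})
    glucan_ca0_mult: float = 0.9
    protein_base_pct: float = 22.0
    #: grams of polyphosphate spectral component per gram of total phosphorus
    polyp_per_phosphorus: float = 3.0
    phosphorus_ca0_mult: float = 0.85
    #: how far the Pi level pushes lipid/phosphorus toward the range ends
    pi_swing: float = 0.8
    #: biological (per-sample) log-normal jitter, s.d. of log
    jitter_sd: float = 0.08
    carotenoid_jitter_sd: float = 0.35
    #: per-spectrum multiplicative gain, s.d. of log
    gain_sd: float = 0.15
    #: polynomial (degree ≤ 3) baseline-drift coefficient scale per block
    drift_scale: dict = field(default_factory=lambda: {"raman": 0.03, "ftir": 0.08})
    #: white-noise s.d. in intensity units
    noise_sd: float = 0.005
    flagged_noise_mult: float = 4.0
    #: heating-emission baseline (Raman only): broad Gaussian rising toward
    #: low wavenumbers, centered off-grid
    heating_amplitude: float = 0.6
    heating_center: float = -600.0
    heating_sigma: float = 900.0
    #: amplitude retained after switching to 200 mW laser power
    reduced_power_mult: float = 0.4
    #: per-component switch/scale, mainly for degenerate test scenarios
    component_scale: dict = field(default_factory=lambda: {c: 1.0 for c in COMPONENTS})

    def validate(self) -> "DesignEffects":
        if self.noise_sd < 0 or self.gain_sd < 0 or self.jitter_sd < 0:
            raise DesignError("noise/gain/jitter scales must be non-negative")
        for d in (self.drift_scale,):
            if any(v < 0 for v in d.values()):
                raise DesignError("drift scales must be non-negative")
        return self


# ---------------------------------------------------------------------------
# dataset synthesis
# ---------------------------------------------------------------------------


def _concentrations(effects: DesignEffects, rng: np.random.Generator) -> pd.DataFrame:
    """Draw true component concentrations for all 72 biological samples."""
    pi_score = {0.5: 1.0, 1.0: 0.0, 4.0: -1.0}
    rows = []
    for strain in STRAINS:
        for pi in PI_LEVELS:
            for ca in CA_LEVELS:
                for rep in (1, 2):
                    z = rng.normal(size=len(COMPONENTS))
                    jit = {
                        c: float(np.exp(z[i] * (
                            effects.carotenoid_jitter_sd
                            if c == "carotenoid"
                            else effects.jitter_sd
                        )))
                        for i, c in enumerate(COMPONENTS)
                    }
                    lo, hi = effects.lipid_range_pct[strain]
                    mid, half = (lo + hi) / 2, (hi - lo) / 2
                    lipid_pct = (mid + half * effects.pi_swing * pi_score[pi]) * jit["lipid"]
                    lo, hi = effects.phosphorus_range_pct[strain]
                    mid, half = (lo + hi) / 2, (hi - lo) / 2
                    phos_pct = (mid - half * effects.pi_swing * pi_score[pi]) * jit["polyphosphate"]
                    if ca == 0:
                        phos_pct *= effects.phosphorus_ca0_mult
                    boost = effects.carotenoid_boost.get(strain, {}).get((pi, ca), 1.0)
                    carot_ugg = effects.carotenoid_base_ugg[strain] * boost * jit["carotenoid"]
                    chitin_pct = (
                        effects.chitin_base_pct[strain]
                        * effects.chitin_pi_mult[pi]
                        * (effects.chitin_ca0_mult if ca == 0 else 1.0)
                        * jit["chitin"]
                    )
                    glucan_pct = (
                        effects.glucan_base_pct
                        * effects.glucan_pi_mult[pi]
                        * (effects.glucan_ca0_mult if ca == 0 else 1.0)
                        * jit["chitosan_glucan"]
                    )
                    protein_pct = effects.protein_base_pct * jit["protein"]
                    # mass closure: dry-weight fractions live on the simplex,
                    # so the structural pool (cell wall + protein) fills the
                    # mass not taken by lipids, polyphosphates and pigments
                    polyp_pct = phos_pct * effects.polyp_per_phosphorus
                    carot_pct = carot_ugg * 1e-4
                    remainder = 100.0 - lipid_pct - polyp_pct - carot_pct
                    if remainder <= 0:
                        raise DesignError(
                            f"composition exceeds 100% dry weight for {strain} "
                            f"(Pi{pi:g}, Ca{ca}, rep {rep})"
                        )
                    structural = chitin_pct + glucan_pct + protein_pct
                    closure = remainder / structural
                    chitin_pct *= closure
                    glucan_pct *= closure
                    protein_pct *= closure
                    cs = effects.component_scale
                    rows.append(
                        {
                            "strain": strain,
                            "pi_level": pi,
                            "ca_level": ca,
                            "bio_rep": rep,
                            "lipid_pct_dw": lipid_pct,
                            "phosphorus_pct_dw": phos_pct,
                            "carotenoid_ug_per_g": carot_ugg,
                            "conc_lipid": lipid_pct / 100.0 * cs["lipid"],
                            "conc_chitin": chitin_pct / 100.0 * cs["chitin"],
                            "conc_chitosan_glucan": glucan_pct / 100.0 * cs["chitosan_glucan"],
                            "conc_protein": protein_pct / 100.0 * cs["protein"],
                            "conc_polyphosphate": polyp_pct / 100.0 * cs["polyphosphate"],
                            "conc_carotenoid": carot_ugg * 1e-6 * cs["carotenoid"],
                        }
                    )
    return pd.DataFrame(rows)


def block_grid(block: str, spacing: float = DEFAULT_SPACING) -> np.ndarray:
    hi, lo = RAMAN_RANGE if block == "raman" else FTIR_RANGE
    return np.arange(hi, lo - 1e-9, -spacing)


def component_profiles(block: str, grid: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Pure spectra of every component of a block, keyed by component."""
    catalog = make_band_catalog(block)
    if grid is None:
        grid = block_grid(block)
    return {
        c: synth_component_spectrum(catalog, c, grid).pure_spectrum
        for c in catalog.components()
    }


def synth_dataset(
    effects: DesignEffects | None = None, seed: int = 0
) -> tuple[SpectraSet, SpectraSet, pd.DataFrame]:
    """Generate the full synthetic study: raman block, ftir block, chemistry.

    Returns 216 spectra per block (72 biological samples × 3 technical
    replicates) with row-aligned metadata and per-row chemistry, plus the
    per-biological-sample chemistry table.  One seed governs everything
    through independent substreams (concentrations, gains, drifts, noise,
    heating), so each source of variation can be zeroed without perturbing
    the others.
    """
    effects = (effects or DesignEffects()).validate()
    ss = np.random.SeedSequence(seed)
    conc_rng, gain_rng, drift_rng, noise_rng, heat_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    chem = _concentrations(effects, conc_rng)

    blocks: dict[str, SpectraSet] = {}
    for block in ("raman", "ftir"):
        grid = block_grid(block)
        profiles = component_profiles(block, grid)
        u = np.linspace(-1.0, 1.0, grid.size)
        heat_shape = np.exp(
            -0.5 * ((grid - effects.heating_center) / effects.heating_sigma) ** 2
        )
        rows, meta_rows, chem_rows = [], [], []
        for _, s in chem.iterrows():
            flagged = _heating_flagged(s["strain"], s["pi_level"], int(s["ca_level"]))
            laser = 200.0 if (block == "raman" and flagged) else 500.0
            clean = np.zeros_like(grid)
            for c in COMPONENTS:
                if c in profiles:
                    clean = clean + s[f"conc_{c}"] * profiles[c]
            for tech in (1, 2, 3):
                gain = float(np.exp(gain_rng.normal() * effects.gain_sd))
                coefs = drift_rng.normal(size=4) * effects.drift_scale[block]
                drift = coefs[0] + coefs[1] * u + coefs[2] * u**2 + coefs[3] * u**3
                amp_jit = heat_rng.normal()
                noise_mult = effects.flagged_noise_mult if (block == "raman" and flagged) else 1.0
                noise = noise_rng.normal(size=grid.size) * effects.noise_sd * noise_mult
                spec = gain * clean + drift + noise
                if block == "raman" and flagged:
                    amp = (
                        effects.heating_amplitude
                        * effects.reduced_power_mult
                        * abs(1.0 + 0.3 * amp_jit)
                    )
                    spec = spec + amp * heat_shape
                rows.append(spec)
                bio_id = (
                    f"{s['strain']}-Pi{s['pi_level']:g}-Ca{int(s['ca_level'])}"
                    f"-B{int(s['bio_rep'])}"
                )
                meta_rows.append(
                    {
                        "sample_id": f"{bio_id}-T{tech}",
                        "strain": s["strain"],
                        "pi_level": float(s["pi_level"]),
                        "ca_level": int(s["ca_level"]),
                        "bio_rep": int(s["bio_rep"]),
                        "tech_rep": tech,
                        "laser_power_mw": laser,
                        "block": block,
                    }
                )
                chem_rows.append(
                    {
                        "lipid_pct_dw": s["lipid_pct_dw"],
                        "phosphorus_pct_dw": s["phosphorus_pct_dw"],
                        "carotenoid_ug_per_g": s["carotenoid_ug_per_g"],
                    }
                )
        blocks[block] = SpectraSet(
            grid,
            np.asarray(rows),
            pd.DataFrame(meta_rows),
            pd.DataFrame(chem_rows),
        ).validate()

    chem = chem.copy()
    chem.insert(
        0,
        "sample_id",
        chem.apply(
            lambda s: f"{s['strain']}-Pi{s['pi_level']:g}-Ca{int(s['ca_level'])}-B{int(s['bio_rep'])}",
            axis=1,
        ),
    )
    return blocks["raman"], blocks["ftir"], chem
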