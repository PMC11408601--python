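"""Synthetic multi-mass NanoSIMS scene generator with known ground truth.

Real acquisitions image nuclei whose newly made RNA (15N-uridine) and DNA
(13C/2H-thymidine or BrdU) labels organize into stereotyped compartments:
DNA-poor nucleoli with intense RNA label, a laminar rim of dense DNA with
suppressed RNA label, textured interior chromatin, and cytoplasm.  This module
builds such scenes from an explicit :class:`SceneSpec`, producing per-species
expected (Poisson mean) count grids, a compartment label map, and the exact
expected enrichment field for every ratio tracer — the oracle against which
the analysis modules are tested — and then samples shot-noise realizations.

Compartment priority when regions overlap:
``nucleolus > lamina > chromatin_focus > nucleoplasm > cytoplasm > background``.
An enrichment multiplier m over natural background means the expected
numerator/denominator ratio in that compartment is ``R0 * (1 + m)``; m = 0 is
natural abundance and m = 1.0 is 100% above background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .ratios import TRACERS, MassImageStack, enrichment_from_ratio

__all__ = [
    "COMPARTMENTS",
    "COMPARTMENT_NAMES",
    "DNA_TRACERS",
    "GeometryError",
    "Ellipse",
    "Disc",
    "ChromatinTexture",
    "SceneSpec",
    "GroundTruth",
    "build_scene",
    "sample_counts",
    "scene_truth_summary",
    "default_scene_spec",
]

#: Compartment label codes used in the ground-truth map (priority-ordered
#: assignment; every pixel gets exactly one code).
COMPARTMENTS = {
    "background": 0,
    "cytoplasm": 1,
    "nucleoplasm": 2,
    "chromatin_focus": 3,
    "lamina": 4,
    "nucleolus": 5,
}
COMPARTMENT_NAMES = {v: k for k, v in COMPARTMENTS.items()}

#: Codes belonging to the nucleus (used for density modulation and area math).
_NUCLEAR_CODES = (2, 3, 4, 5)

#: Tracers whose label follows chromatin density.
DNA_TRACERS = ("13C_DNA", "2H_DNA", "81Br_DNA")


class GeometryError(ValueError):
    """Scene geometry violates its invariants (e.g. nucleolus outside nucleus)."""


@dataclass(frozen=True)
class Ellipse:
    center: tuple          # (row, col) px
    semi_axes: tuple       # (a_row, a_col) px
    orientation_deg: float = 0.0

    def mask(self, shape: tuple) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        th = np.deg2rad(self.orientation_deg)
        u = dr * np.cos(th) + dc * np.sin(th)
        v = -dr * np.sin(th) + dc * np.cos(th)
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def shrunk(self, margin: float) -> "Ellipse":
        a, b = self.semi_axes
        return Ellipse(self.center, (max(a - margin, 0.5), max(b - margin, 0.5)), self.orientation_deg)

    def scaled(self, factor: float) -> "Ellipse":
        a, b = self.semi_axes
        return Ellipse(self.center, (a * factor, b * factor), self.orientation_deg)


@dataclass(frozen=True)
class Disc:
    center: tuple  # (row, col) px
    radius: float  # px, >= 1

    def mask(self, shape: tuple) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class ChromatinTexture:
    """Relative chromatin-density field inside the nucleus.

    Density is a base level plus a seeded smooth correlated random field
    (Gaussian-filtered white noise rescaled to ``amplitude`` standard
    deviation) plus hard discs of dense foci; it is clipped to stay positive.
    DNA-tracer multipliers, the 31P channel, and (inversely) the 32S channel
    are modulated by this field to reproduce graded chromatin density, dense
    condensates, and the P-rich/S-poor chromatin signature.
    """

    base_level: float = 1.0
    amplitude: float = 0.0           # SD of the smooth field (0 = flat)
    correlation_length_px: float = 6.0
    focus_count: int = 0
    focus_amplitude: float = 1.5     # added density inside each focus
    focus_radius_px: float = 3.0
    min_density: float = 0.05


def _default_compartment_enrichment() -> dict:
    # Multipliers over natural background (1.0 = 100% above background),
    # emulating the canonical imaged nucleus: intense nucleolar RNA, silenced
    # RNA / dense DNA at the lamina, graded interior chromatin.
    return {
        "cytoplasm": {"15N_RNA": 0.10, "13C_DNA": 0.0, "2H_DNA": 0.0, "81Br_DNA": 0.0},
        "nucleoplasm": {"15N_RNA": 1.0, "13C_DNA": 1.0, "2H_DNA": 1.0, "81Br_DNA": 1.0},
        "nucleolus": {"15N_RNA": 4.0, "13C_DNA": 0.2, "2H_DNA": 0.2, "81Br_DNA": 0.2},
        "lamina": {"15N_RNA": 0.0, "13C_DNA": 2.0, "2H_DNA": 2.0, "81Br_DNA": 2.0},
        "chromatin_focus": {"15N_RNA": 0.8, "13C_DNA": 2.5, "2H_DNA": 2.5, "81Br_DNA": 2.5},
    }


def _default_structural_levels() -> dict:
    # Expected 31P / 32S counts per pixel per compartment (before density
    # modulation).  Nucleus is P-rich; sulfur marks cell material generally.
    return {
        "background": {"31P": 2.0, "32S": 5.0},
        "cytoplasm": {"31P": 50.0, "32S": 150.0},
        "nucleoplasm": {"31P": 200.0, "32S": 300.0},
        "chromatin_focus": {"31P": 250.0, "32S": 280.0},
        "lamina": {"31P": 300.0, "32S": 250.0},
        "nucleolus": {"31P": 150.0, "32S": 350.0},
    }


def _default_count_budget() -> dict:
    # Expected denominator counts per pixel inside the cell.  CN- at 500/px
    # keeps the pooled nuclear enrichment relative SE under ~2%; the C2- dimer
    # is a majority species and gets a 10x budget, which keeps the measured
    # DNA-enrichment noise small relative to its biological spread.
    return {"12C14N": 500.0, "12C2": 5000.0, "12C2-1H": 5000.0}


@dataclass
class SceneSpec:
    """Ground-truth description of one synthetic acquisition field."""

    image_shape: tuple = (128, 128)
    pixel_size_nm: float = 100.0
    nucleus: Ellipse = field(default_factory=lambda: Ellipse((64, 64), (40, 32)))
    nucleoli: Sequence[Disc] = field(
        default_factory=lambda: (Disc((56, 52), 7.0), Disc((74, 78), 7.0))
    )
    lamina_width_px: float = 3.0
    cell_scale: float = 1.45  # cell boundary = nucleus ellipse scaled by this
    chromatin_texture: ChromatinTexture = field(default_factory=ChromatinTexture)
    compartment_enrichment: dict = field(default_factory=_default_compartment_enrichment)
    count_budget: dict = field(default_factory=_default_count_budget)
    background_budget_fraction: float = 0.05
    structural_levels: dict = field(default_factory=_default_structural_levels)
    br_counts_per_unit: float = 50.0   # expected 81Br counts/px per multiplier unit
    br_background: float = 0.1        # residual 81Br counts/px everywhere
    rna_dna_slope: float | None = None  # couple nucleoplasmic RNA% to DNA% (d%RNA / d%DNA)
    tracers: Sequence[str] = ("15N_RNA", "13C_DNA")
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape must be positive")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.lamina_width_px < 0:
            raise ValueError("lamina_width_px must be >= 0")
        for comp, by_tracer in self.compartment_enrichment.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")
            for tracer, m in by_tracer.items():
                if m < 0:
                    raise ValueError(f"multiplier for {comp}/{tracer} is negative")
        for sp, b in self.count_budget.items():
            if b < 0:
                raise ValueError(f"count budget for {sp!r} is negative")
        for t in self.tracers:
            if t != "81Br_DNA" and t not in TRACERS:
                raise ValueError(f"unknown tracer {t!r}")
        if self.rna_dna_slope is not None and "13C_DNA" not in self.tracers:
            raise ValueError("rna_dna_slope coupling requires the 13C_DNA tracer")
        nuc_mask = self.nucleus.mask(self.image_shape)
        for disc in self.nucleoli:
            if disc.radius < 1:
                raise ValueError("nucleolus radius must be >= 1 px")
            if (disc.mask(self.image_shape) & ~nuc_mask).any():
                raise GeometryError(
                    f"nucleolus at {disc.center} (r={disc.radius}) extends outside the nucleus"
                )
        a, b = self.nucleus.semi_axes
        if self.lamina_width_px >= min(a, b):
            raise GeometryError("lamina_width_px must be smaller than the nuclear semi-axes")


@dataclass
class GroundTruth:
    """Exact expectations for one scene: the oracle for recovery tests."""

    spec: SceneSpec
    compartment_map: np.ndarray            # uint8 codes, see COMPARTMENTS
    expected_counts: dict                  # species -> float grid (Poisson means)
    expected_enrichment: dict              # ratio tracer -> percent grid
    density: np.ndarray                    # chromatin density field (1.0 outside nucleus)

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.compartment_map == COMPARTMENTS[name]

    @property
    def nucleus_mask(self) -> np.ndarray:
        return np.isin(self.compartment_map, _NUCLEAR_CODES)


def _chromatin_density(spec: SceneSpec, nucleoplasm_like: np.ndarray):
    """Density field and focus mask, seeded by spec.seed."""
    tex = spec.chromatin_texture
    rng = np.random.default_rng(spec.seed)
    d = np.full(spec.image_shape, tex.base_level, dtype=float)
    if tex.amplitude > 0:
        noise = rng.standard_normal(spec.image_shape)
        smooth = ndimage.gaussian_filter(noise, sigma=tex.correlation_length_px)
        sd = smooth.std()
        if sd > 0:
            d += tex.amplitude * smooth / sd
    focus_mask = np.zeros(spec.image_shape, dtype=bool)
    if tex.focus_count > 0:
        candidates = np.argwhere(nucleoplasm_like)
        if len(candidates):
            picks = candidates[rng.choice(len(candidates), size=tex.focus_count)]
            for r, c in picks:
                disc = Disc((float(r), float(c)), tex.focus_radius_px).mask(spec.image_shape)
                focus_mask |= disc & nucleoplasm_like
            d[focus_mask] += tex.focus_amplitude
    np.clip(d, tex.min_density, None, out=d)
    return d, focus_mask


def build_scene(spec: SceneSpec) -> GroundTruth:
    """Rasterize a scene spec into compartments, expected counts and enrichments.

    Deterministic given the spec: the only randomness (texture, focus
    placement) is driven by ``spec.seed``.
    """
    spec.validate()
    shape = spec.image_shape

    nucleus = spec.nucleus.mask(shape)
    inner = spec.nucleus.shrunk(spec.lamina_width_px).mask(shape)
    lamina = nucleus & ~inner if spec.lamina_width_px > 0 else np.zeros(shape, bool)
    cell = spec.nucleus.scaled(spec.cell_scale).mask(shape)
    nucleoli = np.zeros(shape, bool)
    for disc in spec.nucleoli:
        nucleoli |= disc.mask(shape)

    density, focus_mask = _chromatin_density(spec, inner & ~nucleoli)

    # priority: nucleolus > lamina > chromatin_focus > nucleoplasm > cytoplasm > background
    cmap = np.zeros(shape, dtype=np.uint8)
    cmap[cell] = COMPARTMENTS["cytoplasm"]
    cmap[nucleus] = COMPARTMENTS["nucleoplasm"]
    cmap[focus_mask & nucleus] = COMPARTMENTS["chromatin_focus"]
    cmap[lamina] = COMPARTMENTS["lamina"]
    cmap[nucleoli] = COMPARTMENTS["nucleolus"]

    in_nucleus = np.isin(cmap, _NUCLEAR_CODES)
    density = np.where(in_nucleus, density, 1.0)
    # Density modulation applies outside the nucleolus (nucleoli are DNA-poor
    # at fixed level); renormalize to mean 1 over the modulated region so
    # compartment multipliers keep their meaning on average.
    mod_region = in_nucleus & (cmap != COMPARTMENTS["nucleolus"])
    if mod_region.any():
        density[mod_region] /= density[mod_region].mean()

    def multiplier_field(tracer: str) -> np.ndarray:
        m = np.zeros(shape, dtype=float)
        for comp, code in COMPARTMENTS.items():
            m[cmap == code] = spec.compartment_enrichment.get(comp, {}).get(tracer, 0.0)
        if tracer in DNA_TRACERS:
            m[mod_region] *= density[mod_region]
        return m

    fields = {t: multiplier_field(t) for t in spec.tracers}

    if spec.rna_dna_slope is not None and "15N_RNA" in fields:
        # Couple the nucleoplasmic RNA enrichment linearly to the realized DNA
        # enrichment field: E_rna = E_base + slope * (E_dna - mean(E_dna)).
        npl = cmap == COMPARTMENTS["nucleoplasm"]
        e_dna = 100.0 * fields["13C_DNA"]
        e_rna = 100.0 * fields["15N_RNA"]
        centered = e_dna[npl] - e_dna[npl].mean()
        coupled = e_rna[npl] + spec.rna_dna_slope * centered
        if (coupled < 0).any():
            raise ValueError(
                "rna_dna_slope coupling drives expected RNA enrichment negative; "
                "raise the nucleoplasmic 15N_RNA multiplier or reduce texture amplitude"
            )
        e_rna[npl] = coupled
        fields["15N_RNA"] = e_rna / 100.0

    expected_counts: dict = {}
    expected_enrichment: dict = {}
    budget_scale = np.where(cell, 1.0, spec.background_budget_fraction)

    for tracer in spec.tracers:
        if tracer == "81Br_DNA":
            expected_counts["81Br"] = (
                spec.br_counts_per_unit * fields[tracer] + spec.br_background
            )
            continue
        rd = TRACERS[tracer]
        den_budget = spec.count_budget.get(rd.denominator)
        if den_budget is None:
            raise ValueError(f"count_budget missing denominator species {rd.denominator!r}")
        den = den_budget * budget_scale
        num = den * rd.r0 * (1.0 + fields[tracer])
        # species may be shared between tracers; keep the first definition
        expected_counts.setdefault(rd.denominator, den)
        expected_counts[rd.numerator] = num
        expected_enrichment[tracer] = 100.0 * fields[tracer]

    p = np.zeros(shape, dtype=float)
    s = np.zeros(shape, dtype=float)
    for comp, code in COMPARTMENTS.items():
        levels = spec.structural_levels.get(comp, {"31P": 0.0, "32S": 0.0})
        sel = cmap == code
        p[sel] = levels.get("31P", 0.0)
        s[sel] = levels.get("32S", 0.0)
    p[mod_region] *= density[mod_region]
    s[mod_region] /= np.clip(density[mod_region], 0.5, 2.0)
    expected_counts["31P"] = p
    expected_counts["32S"] = s

    for sp, grid in expected_counts.items():
        if (grid < 0).any():
            raise ValueError(f"negative expected counts for species {sp!r}")

    return GroundTruth(
        spec=spec,
        compartment_map=cmap,
        expected_counts=expected_counts,
        expected_enrichment=expected_enrichment,
        density=density,
    )


def sample_counts(truth: GroundTruth, seed: int) -> MassImageStack:
    """Draw one Poisson shot-noise realization of a scene.

    Each pixel of each species is an independent Poisson draw with the
    expected-count mean; identical seeds give bit-identical stacks (species
    are sampled in sorted name order).
    """
    rng = np.random.default_rng(seed)
    channels = {
        sp: rng.poisson(truth.expected_counts[sp]).astype(np.int64)
        for sp in sorted(truth.expected_counts)
    }
    return MassImageStack(
        channels=channels,
        pixel_size_nm=truth.spec.pixel_size_nm,
        metadata={"seed": int(seed), "scene_seed": int(truth.spec.seed)},
    )


def scene_truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Per-compartment areas and expected mean enrichments (the test oracle)."""
    px_um2 = (truth.spec.pixel_size_nm / 1000.0) ** 2
    rows = []
    for code in np.unique(truth.compartment_map):
        sel = truth.compartment_map == code
        row = {
            "compartment": COMPARTMENT_NAMES[int(code)],
            "area_px": int(sel.sum()),
            "area_um2": float(sel.sum() * px_um2),
        }
        for tracer, grid in truth.expected_enrichment.items():
            row[f"expected_enrichment_pct_{tracer}"] = float(grid[sel].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def default_scene_spec(**overrides) -> SceneSpec:
    """The canonical imaged-nucleus scene with optional field overrides."""
    spec = SceneSpec()
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise TypeError(f"SceneSpec has no field {key!r}")
        setattr(spec, key, value)
    return spec


def spec_to_dict(spec: SceneSpec) -> dict:
    """JSON-serializable echo of a scene spec (for sidecars and manifests)."""
    d = asdict(spec)
    d["nucleoli"] = [asdict(n) for n in spec.nucleoli]
    return d
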