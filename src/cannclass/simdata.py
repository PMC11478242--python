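"""Synthetic EI-spectrum generator for exercising the classification cascade.

Each compound class is composed from structural building blocks (core, head,
tail for synthetic cannabinoids; standalone profiles for classical
cannabinoids and the "other drug" classes) whose characteristic fragment m/z
values follow the diagnostic ions reported for these drug classes in the
forensic literature: indole cores fragment at m/z 144 (145 for
indazole/azaindole), naphthyl heads at 127/155, the 4-fluorobenzyl (FUB)
tail at 109/252, 5-fluoropentyl tails shift the core+tail fragment from
214/215 to 232/233, classical cannabinoids show 41/69/73/91/175/231/260,
and so on. Peak intensities and presence probabilities are synthetic design
choices (not measured values); the generator aims for enough statistical
structure to exercise the pipeline, not for physical fidelity.

Noise model: multiplicative lognormal intensity jitter, random low-intensity
noise peaks at m/z positions not used by the class profile, and independent
per-peak dropout. With jitter 0, dropout 0 and no noise peaks, members of a
class are identical and the classes are linearly separable in binned space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .msdata import ClassAnnotation, MassSpectrum, SpectrumMatrix, build_matrix

# ---------------------------------------------------------------------------
# Fragment profiles: (m/z, mean relative intensity, presence probability)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentPeak:
    mz: int
    intensity: float
    presence: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.presence <= 1.0):
            raise ValueError("presence probability must lie in [0, 1]")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class FragmentProfile:
    """Named set of characteristic fragment peaks of one structural class."""

    name: str
    peaks: tuple[FragmentPeak, ...]


def _prof(name, *pairs):
    return FragmentProfile(name, tuple(FragmentPeak(mz, i) for mz, i in pairs))


#: building-block fragment tables (m/z, mean intensity). Core+tail composite
#: fragments (214/215, 232/233, FUB 252/253, 284/285) are added by
#: :func:`compose_profile` so core, head and tail stay chemically coherent.
PROFILES: dict[str, FragmentProfile] = {
    "indole_core": _prof("indole_core", (144, 100)),
    "indazole_core": _prof("indazole_core", (145, 100)),
    "azaindole_core": _prof("azaindole_core", (145, 100)),
    "naphthoylpyrrole_core": _prof(
        "naphthoylpyrrole_core", (66, 30), (127, 60), (155, 80), (219, 45), (247, 100)
    ),
    "naphthyl_head": _prof("naphthyl_head", (127, 70), (155, 85)),
    "generic_head": _prof("generic_head", (119, 55)),
    "fub_tail": _prof("fub_tail", (109, 95), (252, 60)),
    "classical": _prof(
        "classical",
        (41, 35), (69, 40), (73, 25), (91, 45), (175, 30), (231, 100), (260, 55),
    ),
    "fentanyl_like": _prof(
        "fentanyl_like", (42, 30), (77, 25), (91, 40), (95, 20), (160, 35), (259, 100)
    ),
    "cathinone_like": _prof(
        "cathinone_like", (44, 100), (65, 20), (77, 35), (91, 45), (95, 25)
    ),
    "tryptamine_like": _prof(
        "tryptamine_like", (44, 100), (77, 25), (160, 40), (161, 30)
    ),
    "phenethylamine_like": _prof(
        "phenethylamine_like", (44, 100), (77, 40), (91, 50), (259, 20)
    ),
    "opioid_like": _prof(
        "opioid_like", (42, 60), (44, 50), (70, 40), (77, 30), (91, 35), (272, 100)
    ),
}

CORES = ("indole", "indazole", "azaindole", "naphthoylpyrrole")
TAILS = ("pentyl", "5f_pentyl", "fub")


@dataclass(frozen=True)
class CompoundClass:
    """A simulated compound family: either an 'other drug' profile, the
    classical-cannabinoid profile, or a synthetic cannabinoid composed of
    core + head + tail."""

    name: str
    is_cannabinoid: bool
    is_classical: bool | None = None
    core: str | None = None           # one of CORES
    head: str | None = None           # "naphthyl" or "other"
    tail: str | None = None           # one of TAILS
    other_profile: str | None = None  # profile key for non-cannabinoids

    def __post_init__(self):
        if self.is_cannabinoid:
            if self.is_classical is None:
                raise ValueError(f"{self.name}: cannabinoid needs is_classical")
            if self.is_classical:
                if self.core or self.head or self.tail:
                    raise ValueError(
                        f"{self.name}: classical cannabinoids take no core/head/tail"
                    )
            else:
                if self.core not in CORES:
                    raise ValueError(f"{self.name}: synthetic core must be one of {CORES}")
                if self.head not in ("naphthyl", "other"):
                    raise ValueError(f"{self.name}: head must be 'naphthyl' or 'other'")
                if self.tail not in TAILS:
                    raise ValueError(f"{self.name}: tail must be one of {TAILS}")
        else:
            if self.other_profile not in PROFILES:
                raise ValueError(f"{self.name}: unknown other_profile")
            if self.is_classical is not None or self.core or self.head or self.tail:
                raise ValueError(f"{self.name}: non-cannabinoid takes no subgroup fields")

    def annotation(self, compound_id: str) -> ClassAnnotation:
        if not self.is_cannabinoid:
            return ClassAnnotation(compound_id=compound_id, is_cannabinoid=False)
        if self.is_classical:
            return ClassAnnotation(
                compound_id=compound_id, is_cannabinoid=True, is_classical=True
            )
        return ClassAnnotation(
            compound_id=compound_id,
            is_cannabinoid=True,
            is_classical=False,
            core_group=self.core,
            head_is_naphthyl=self.head == "naphthyl",
            tail_is_fub=self.tail == "fub",
            tail_is_5f_pentyl=self.tail == "5f_pentyl",
        )


def compose_profile(cls: CompoundClass) -> tuple[FragmentPeak, ...]:
    """Assemble the characteristic peak list of a compound class.

    Core+tail composite fragments follow the fluorination of the tail: a
    pentyl tail gives core fragments 214 (indole) / 215 (indazole,
    azaindole); a 5-fluoropentyl tail shifts them to 232/233; the FUB tail
    gives 252/253. Naphthyl heads on indole/indazole-type cores add the
    tail-loss fragments 284/285.
    """
    if not cls.is_cannabinoid:
        return PROFILES[cls.other_profile].peaks
    if cls.is_classical:
        return PROFILES["classical"].peaks
    peaks: list[FragmentPeak] = list(PROFILES[f"{cls.core}_core"].peaks)
    one_up = cls.core in ("indazole", "azaindole")  # extra ring N: +1 m/z
    if cls.core != "naphthoylpyrrole":
        if cls.tail == "pentyl":
            peaks.append(FragmentPeak(214 + one_up, 45))
            if cls.core == "indole":
                peaks.append(FragmentPeak(186, 35))  # n-pentylindole fragment
        elif cls.tail == "5f_pentyl":
            peaks.append(FragmentPeak(232 + one_up, 55))
        elif cls.tail == "fub":
            # FUB cleavage ion 109 plus the core+FUB fragment (252 on indole
            # cores, 253 on the one-m/z-heavier indazole/azaindole cores)
            peaks.append(FragmentPeak(109, 95))
            peaks.append(FragmentPeak(252 + one_up, 60))
        if cls.head == "naphthyl":
            peaks.extend(PROFILES["naphthyl_head"].peaks)
            peaks.append(FragmentPeak(284 + one_up, 50))
        else:
            peaks.extend(PROFILES["generic_head"].peaks)
    # merge collisions (e.g. FUB 252 with indazole core+tail 253 never collide,
    # but be safe): sum intensities, max presence
    merged: dict[int, FragmentPeak] = {}
    for pk in peaks:
        if pk.mz in merged:
            old = merged[pk.mz]
            merged[pk.mz] = FragmentPeak(
                pk.mz, old.intensity + pk.intensity, max(old.presence, pk.presence)
            )
        else:
            merged[pk.mz] = pk
    return tuple(merged[mz] for mz in sorted(merged))


#: default class inventory: 8 cannabinoid families (1 classical + 7 synthetic
#: core/head/tail combinations) and 4 "other drug" classes, mirroring the
#: composition of a forensic screening library at reduced scale
DEFAULT_CLASSES: tuple[CompoundClass, ...] = (
    CompoundClass("classical", True, True),
    CompoundClass("indole_naphthyl_pentyl", True, False, "indole", "naphthyl", "pentyl"),
    CompoundClass("indole_naphthyl_5f", True, False, "indole", "naphthyl", "5f_pentyl"),
    CompoundClass("indole_other_fub", True, False, "indole", "other", "fub"),
    CompoundClass("indazole_other_5f", True, False, "indazole", "other", "5f_pentyl"),
    CompoundClass("indazole_naphthyl_pentyl", True, False, "indazole", "naphthyl", "pentyl"),
    CompoundClass("azaindole_other_pentyl", True, False, "azaindole", "other", "pentyl"),
    CompoundClass("naphthoylpyrrole", True, False, "naphthoylpyrrole", "naphthyl", "pentyl"),
    CompoundClass("fentanyl_like", False, other_profile="fentanyl_like"),
    CompoundClass("cathinone_like", False, other_profile="cathinone_like"),
    CompoundClass("tryptamine_like", False, other_profile="tryptamine_like"),
    CompoundClass("phenethylamine_like", False, other_profile="phenethylamine_like"),
)


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset.

    Defaults give ~95% effective peak presence (dropout 0.05), 15 noise
    peaks of intensity at most 20 (relative scale), and lognormal intensity
    jitter sigma 0.15; ``noiseless()`` zeroes all three, under which class
    members are identical and the classes linearly separable.

    The default 32 training compounds per class (384 spectra over the 12
    default classes) mirror the scale of the real training library (~434
    spectra); GA variable selection needs training populations of that
    order per node, or it memorizes chance noise-peak alignments and
    held-out accuracy degrades.
    """

    n_train_per_class: int = 32
    n_test_per_class: int = 8
    intensity_jitter: float = 0.15
    n_noise_peaks: int = 15
    noise_intensity_max: float = 20.0
    peak_dropout: float = 0.05
    seed: int = 0
    mz_lo: int = 40
    mz_hi: int = 300

    def __post_init__(self):
        if self.intensity_jitter < 0:
            raise ValueError("intensity jitter must be >= 0")
        if not (0.0 <= self.peak_dropout < 1.0):
            raise ValueError("peak dropout must lie in [0, 1)")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")

    @classmethod
    def noiseless(cls, **kw) -> "SimConfig":
        kw.setdefault("intensity_jitter", 0.0)
        kw.setdefault("n_noise_peaks", 0)
        kw.setdefault("peak_dropout", 0.0)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "n_train_per_class": self.n_train_per_class,
            "n_test_per_class": self.n_test_per_class,
            "intensity_jitter": self.intensity_jitter,
            "n_noise_peaks": self.n_noise_peaks,
            "noise_intensity_max": self.noise_intensity_max,
            "peak_dropout": self.peak_dropout,
            "seed": self.seed,
            "mz_lo": self.mz_lo,
            "mz_hi": self.mz_hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


def generate_spectrum(
    cls: CompoundClass,
    cfg: SimConfig,
    rng: np.random.Generator,
    compound_id: str,
    source: str = "sim",
) -> tuple[MassSpectrum, ClassAnnotation]:
    """Draw one synthetic spectrum plus its ground-truth annotation.

    Characteristic peaks are kept with probability presence*(1-dropout) and
    jittered multiplicatively; noise peaks land only on m/z positions not
    used by the class profile. The spectrum is returned base-peak-normalized
    to 100.
    """
    profile = compose_profile(cls)
    char_mz = {pk.mz for pk in profile}
    peaks: list[tuple[float, float]] = []
    for pk in profile:
        p_keep = pk.presence * (1.0 - cfg.peak_dropout)
        if rng.random() >= p_keep:
            continue
        inten = pk.intensity
        if cfg.intensity_jitter > 0:
            inten *= float(np.exp(rng.normal(0.0, cfg.intensity_jitter)))
        peaks.append((float(pk.mz), inten))
    if not peaks:
        # never emit an empty spectrum: keep the profile's base peak
        base = max(profile, key=lambda pk: pk.intensity)
        peaks.append((float(base.mz), base.intensity))
    if cfg.n_noise_peaks > 0:
        candidates = np.array(
            [m for m in range(cfg.mz_lo, cfg.mz_hi + 1) if m not in char_mz]
        )
        chosen = rng.choice(candidates, size=min(cfg.n_noise_peaks, len(candidates)),
                            replace=False)
        for m in chosen:
            peaks.append((float(m), float(rng.uniform(1.0, cfg.noise_intensity_max))))
    top = max(i for _, i in peaks)
    peaks = [(m, 100.0 * i / top) for m, i in peaks]
    spectrum = MassSpectrum(
        compound_id=compound_id, name=compound_id, peaks=tuple(peaks), source=source
    )
    return spectrum, cls.annotation(compound_id)


def generate_dataset(
    cfg: SimConfig,
    classes: tuple[CompoundClass, ...] = DEFAULT_CLASSES,
) -> tuple[SpectrumMatrix, SpectrumMatrix]:
    """Generate disjoint training and test spectrum matrices.

    Compound ids never overlap between splits; with the default class
    inventory every cascade node sees both of its labels in both splits.
    """
    if cfg.n_train_per_class < 4 or cfg.n_test_per_class < 4:
        raise ValueError("need at least 4 compounds per class in each split")
    rng = np.random.default_rng(cfg.seed)
    splits = {}
    for split, n in (("train", cfg.n_train_per_class), ("test", cfg.n_test_per_class)):
        spectra, anns = [], []
        for cls in classes:
            for i in range(n):
                cid = f"{cls.name}-{split}-{i:03d}"
                s, a = generate_spectrum(cls, cfg, rng, cid, source=split)
                spectra.append(s)
                anns.append(a)
        splits[split] = build_matrix(spectra, anns, lo=cfg.mz_lo, hi=cfg.mz_hi)
    return splits["train"], splits["test"]


def dataset_spectra(
    cfg: SimConfig,
    classes: tuple[CompoundClass, ...] = DEFAULT_CLASSES,
):
    """Like :func:`generate_dataset` but returning raw spectra + annotations
    per split (for writing MSP/CSV files). Uses the same draw order, so the
    binned matrices of :func:`generate_dataset` match exactly."""
    if cfg.n_train_per_class < 4 or cfg.n_test_per_class < 4:
        raise ValueError("need at least 4 compounds per class in each split")
    rng = np.random.default_rng(cfg.seed)
    out = {}
    for split, n in (("train", cfg.n_train_per_class), ("test", cfg.n_test_per_class)):
        spectra, anns = [], []
        for cls in classes:
            for i in range(n):
                cid = f"{cls.name}-{split}-{i:03d}"
                s, a = generate_spectrum(cls, cfg, rng, cid, source=split)
                spectra.append(s)
                anns.append(a)
        out[split] = (spectra, anns)
    return out["train"], out["test"]
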