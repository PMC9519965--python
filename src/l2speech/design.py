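"""Study design and synthesis specifications.

The default design mirrors a pre/post stimulation study of second-language
(L2) English spoken by native Hebrew speakers: 36 participants split evenly
into an active and a sham stimulation group, two recording sessions (pre and
post training), and a word list built from seven phoneme contrasts — three
vowel contrasts (/i/-/ɪ/, /ɛ/-/æ/, /ʌ/-/ɑ/) and four consonant contrasts
(/z/-/ð/, /d/-/ð/, /s/-/θ/, /t/-/θ/) — with five word tokens per phoneme,
i.e. 35 minimal pairs and 70 words, each imitated three times per session.

Phonemes are labelled with lower-case ARPABET-style codes so that every
identifier is plain ASCII: ``iy ih eh ae ah aa`` for the vowels and
``z dh d th s t`` for the consonants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "StudyDesign",
    "VowelSpec",
    "FricativeSpec",
    "BehavioralEffectModel",
    "ProductionEffectModel",
    "DEFAULT_VOWEL_SPECS",
    "DEFAULT_FRICATIVE_SPECS",
    "VOWELS",
    "CONSONANTS",
    "IPA",
]

#: ARPABET-ish code -> IPA, for reports.
IPA = {
    "iy": "i", "ih": "ɪ", "eh": "ɛ", "ae": "æ", "ah": "ʌ", "aa": "ɑ",
    "z": "z", "dh": "ð", "d": "d", "th": "θ", "s": "s", "t": "t",
}

VOWELS = ("iy", "ih", "eh", "ae", "ah", "aa")
CONSONANTS = ("z", "dh", "d", "th", "s", "t")

_VOWEL_CONTRASTS = (("iy", "ih"), ("eh", "ae"), ("ah", "aa"))
_CONSONANT_CONTRASTS = (("z", "dh"), ("d", "dh"), ("s", "th"), ("t", "th"))


def _contrast_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the study.

    Under the defaults the word list has ``7 contrasts x 2 phonemes x 5
    tokens = 70`` words; per session each participant produces every word
    ``repetitions`` times, giving ``36 x 2 x 30 x 3 = 6480`` vowel tokens and
    ``36 x 2 x 40 x 3 = 8640`` consonant tokens.
    """

    n_participants: int = 36
    n_active: int = 18
    tokens_per_phoneme: int = 5
    repetitions: int = 3
    sessions: tuple[str, ...] = ("pre", "post")
    vowel_contrasts: tuple[tuple[str, str], ...] = _VOWEL_CONTRASTS
    consonant_contrasts: tuple[tuple[str, str], ...] = _CONSONANT_CONTRASTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2 or not 0 < self.n_active < self.n_participants:
            raise ValueError("need at least one participant per group")
        if self.tokens_per_phoneme < 1 or self.repetitions < 1:
            raise ValueError("tokens_per_phoneme and repetitions must be >= 1")

    # -- participants ------------------------------------------------------
    @property
    def participants(self) -> list[str]:
        width = len(str(self.n_participants))
        return [f"p{i + 1:0{width}d}" for i in range(self.n_participants)]

    def group_of(self, participant: str) -> str:
        idx = self.participants.index(participant)
        return "active" if idx < self.n_active else "sham"

    def sex_of(self, participant: str) -> str:
        # Alternating assignment keeps the sexes balanced within each group.
        idx = self.participants.index(participant)
        return "male" if idx % 2 == 0 else "female"

    # -- word list ---------------------------------------------------------
    @property
    def contrasts(self) -> tuple[tuple[str, str], ...]:
        return self.vowel_contrasts + self.consonant_contrasts

    @property
    def contrast_names(self) -> list[str]:
        return [_contrast_name(c) for c in self.contrasts]

    def words(self) -> list[dict]:
        """One record per word: word id, phoneme, contrast, pair index."""
        rows = []
        for pair in self.contrasts:
            name = _contrast_name(pair)
            is_vowel = pair in self.vowel_contrasts
            for phoneme in pair:
                for j in range(1, self.tokens_per_phoneme + 1):
                    # /dh/ and /th/ each occur in two contrasts; every
                    # contrast has its own five word pairs, so the word id
                    # carries the contrast to stay unique.
                    rows.append(
                        {
                            "word": f"{name}_{phoneme}{j}",
                            "phoneme": phoneme,
                            "contrast": name,
                            "pair_index": j,
                            "is_vowel": is_vowel,
                        }
                    )
        return rows

    # -- closed-form counts ------------------------------------------------
    @property
    def n_words(self) -> int:
        return len(self.contrasts) * 2 * self.tokens_per_phoneme

    @property
    def n_minimal_pairs(self) -> int:
        return len(self.contrasts) * self.tokens_per_phoneme

    @property
    def n_vowel_words(self) -> int:
        return len(self.vowel_contrasts) * 2 * self.tokens_per_phoneme

    @property
    def n_consonant_words(self) -> int:
        return len(self.consonant_contrasts) * 2 * self.tokens_per_phoneme

    @property
    def n_vowel_tokens(self) -> int:
        return (
            self.n_participants
            * len(self.sessions)
            * self.repetitions
            * self.n_vowel_words
        )

    @property
    def n_consonant_tokens(self) -> int:
        return (
            self.n_participants
            * len(self.sessions)
            * self.repetitions
            * self.n_consonant_words
        )

    @property
    def n_tokens(self) -> int:
        return self.n_vowel_tokens + self.n_consonant_tokens


@dataclass(frozen=True)
class VowelSpec:
    """Ground-truth acoustic targets for one vowel category.

    Frequencies are on the female scale; male speakers are synthesized with
    F1 divided by 1.183 and F2-F4 divided by 1.172 (the inverse of the fixed
    normalization factors) and a lower fundamental. Standard deviations
    split into a between-speaker component (a speaker's habitual target) and
    a within-speaker component (token-to-token scatter).
    """

    phoneme: str
    f1_mean: float
    f2_mean: float
    f3_mean: float = 2900.0
    f4_mean: float = 4000.0
    f0: float = 210.0  # female default; male uses f0 * 120/210
    bandwidths: tuple[float, ...] = (80.0, 90.0, 120.0, 150.0)
    duration_mean: float = 0.15
    duration_sd: float = 0.03
    between_sd_frac: float = 0.04
    within_sd_frac: float = 0.02

    def __post_init__(self) -> None:
        if not self.f1_mean < self.f2_mean < self.f3_mean < self.f4_mean:
            raise ValueError(f"{self.phoneme}: formant means must be increasing")
        if min(self.bandwidths) <= 0 or self.f0 <= 0:
            raise ValueError("bandwidths and f0 must be positive")
        if self.duration_sd < 0 or self.between_sd_frac < 0 or self.within_sd_frac < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class FricativeSpec:
    """Band-noise model of a consonant for centre-of-gravity analysis.

    The token is white noise shaped by a band filter from ``band_low`` to
    ``band_high`` whose amplitude rises or falls at ``spectral_tilt``
    dB/octave across the band; the ground-truth COG follows analytically
    from that power response. Stops are modelled as short bursts of the same
    kind of noise.
    """

    phoneme: str
    band_low: float
    band_high: float
    spectral_tilt: float = 0.0  # dB/octave across the band
    duration_mean: float = 0.12
    duration_sd: float = 0.02
    duration_min: float = 0.04
    band_jitter_frac: float = 0.03  # lognormal sd of band-edge scaling per token

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError(f"{self.phoneme}: need 0 < band_low < band_high")
        if self.band_jitter_frac < 0 or self.duration_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class BehavioralEffectModel:
    """Generative model for AXB discrimination responses.

    ``baseline_accuracy`` is the per-contrast probability of a correct
    response in every cell except active/post, where ``accuracy_shift`` is
    added (clipped to [0, 1]). The default shifts mirror the study's
    direction of effects: the active group improves on a subset of
    contrasts, the sham group is flat; magnitudes are free parameters of the
    generator, not estimates.
    """

    baseline_accuracy: dict = field(
        default_factory=lambda: {
            "iy-ih": 0.80, "eh-ae": 0.65, "ah-aa": 0.65,
            "z-dh": 0.70, "d-dh": 0.75, "s-th": 0.65, "t-th": 0.70,
        }
    )
    accuracy_shift: dict = field(
        default_factory=lambda: {
            "iy-ih": 0.0, "eh-ae": 0.15, "ah-aa": 0.15,
            "z-dh": 0.12, "d-dh": 0.0, "s-th": 0.15, "t-th": 0.12,
        }
    )
    rt_mean: float = 900.0
    rt_sd: float = 250.0
    rt_min: float = 200.0
    rt_max: float = 2500.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for c, p in self.baseline_accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline accuracy for {c} outside [0, 1]")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate outside [0, 1]")
        if self.rt_sd < 0 or self.rt_min >= self.rt_max:
            raise ValueError("invalid RT parameters")

    @classmethod
    def null(cls) -> "BehavioralEffectModel":
        """Zero group-by-session effect everywhere (type-I error studies)."""
        model = cls()
        return replace(model, accuracy_shift={c: 0.0 for c in model.accuracy_shift})

    def p_correct(self, contrast: str, group: str, session: str) -> float:
        p = self.baseline_accuracy[contrast]
        if group == "active" and session == "post":
            p += self.accuracy_shift.get(contrast, 0.0)
        return float(min(1.0, max(0.0, p)))


@dataclass(frozen=True)
class ProductionEffectModel:
    """Group-by-session shifts applied to synthesized productions.

    ``f2_shift_hz`` moves the active group's post-session F2 target for the
    listed vowels (positive = towards a higher, more native-like F2);
    ``cog_shift_hz`` scales into a band-edge shift for the listed
    consonants. Defaults mirror the reported direction of effects (change in
    /i/, /ɛ/, /ʌ/ F2 and in /z/, /s/ COG for the active group only).
    """

    f2_shift_hz: dict = field(
        default_factory=lambda: {"iy": 60.0, "eh": 60.0, "ah": -60.0}
    )
    cog_shift_hz: dict = field(default_factory=lambda: {"z": 300.0, "s": 300.0})

    @classmethod
    def null(cls) -> "ProductionEffectModel":
        return cls(f2_shift_hz={}, cog_shift_hz={})


# F2 means seeded from the study's pre-training values (averaged over the two
# groups, female scale); F1/F3/F4 are standard American-English reference
# values on the same scale.
DEFAULT_VOWEL_SPECS: dict[str, VowelSpec] = {
    "iy": VowelSpec("iy", f1_mean=310.0, f2_mean=2585.0),
    "ih": VowelSpec("ih", f1_mean=430.0, f2_mean=2322.0),
    "eh": VowelSpec("eh", f1_mean=580.0, f2_mean=2130.5),
    "ae": VowelSpec("ae", f1_mean=690.0, f2_mean=1995.0),
    "ah": VowelSpec("ah", f1_mean=640.0, f2_mean=1600.0),
    "aa": VowelSpec("aa", f1_mean=750.0, f2_mean=1391.5),
}

# Band-noise parameters chosen so sibilants sit high (COG > 5 kHz), dental
# fricatives low and diffuse, and stops are short bursts; values assume a
# 16 kHz synthesis rate (band_high < Nyquist).
DEFAULT_FRICATIVE_SPECS: dict[str, FricativeSpec] = {
    "s": FricativeSpec("s", 3500.0, 7800.0, spectral_tilt=2.0, duration_mean=0.14),
    "z": FricativeSpec("z", 3000.0, 7500.0, spectral_tilt=0.0, duration_mean=0.10),
    "th": FricativeSpec("th", 1000.0, 7000.0, spectral_tilt=-3.0, duration_mean=0.12),
    "dh": FricativeSpec("dh", 800.0, 6000.0, spectral_tilt=-4.0, duration_mean=0.08),
    "t": FricativeSpec(
        "t", 2500.0, 7800.0, duration_mean=0.06, duration_sd=0.01, duration_min=0.03
    ),
    "d": FricativeSpec(
        "d", 800.0, 5000.0, spectral_tilt=-2.0,
        duration_mean=0.05, duration_sd=0.01, duration_min=0.03,
    ),
}
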