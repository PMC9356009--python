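"""Stimulus and cytokine panel metadata.

The study design stimulates PBMCs with a media control plus 15 stimuli —
3 live respiratory viruses, 2 live bacteria, 9 TLR ligands and the T-cell
mitogen PHA — and measures 28 secreted cytokines per well.  When too few
cells were available for the full panel, stimuli were used in a fixed rank
order, so per-stimulus missingness grows down the rank list; those published
mean missing rates are stored on the panel and drive the synthetic
missingness model.

Cytokines carry a functional-group label (anti-viral/IFN-induced,
pro-inflammatory, T-cell derived, weak/not induced) and a per-batch lower
detection limit (LOD) in pg/mL; sub-LOD measurements are recorded as half
the LOD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MEDIA = "media"

STIMULUS_GROUPS = ("viral", "bacterial", "tcell", "media")
CYTOKINE_GROUPS = ("anti_viral", "pro_inflammatory", "t_cell", "weak")


@dataclass(frozen=True)
class StimulusEntry:
    name: str
    group: str
    rank: int
    target_missing_rate: float  # fraction in [0, 1]


@dataclass(frozen=True)
class StimulusPanel:
    """Ordered stimulus panel with the rank-order missingness targets."""

    entries: tuple[StimulusEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("stimulus names must be unique")
        media = [e for e in self.entries if e.group == "media"]
        if len(media) != 1:
            raise ValueError("exactly one media entry required")
        ranks = sorted(e.rank for e in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        for e in self.entries:
            if e.group not in STIMULUS_GROUPS:
                raise ValueError(f"unknown stimulus group {e.group!r}")
            if not 0.0 <= e.target_missing_rate <= 1.0:
                raise ValueError("target_missing_rate must be in [0, 1]")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def media_name(self) -> str:
        return next(e.name for e in self.entries if e.group == "media")

    def by_rank(self) -> list[StimulusEntry]:
        return sorted(self.entries, key=lambda e: e.rank)

    def rank_of(self, name: str) -> int:
        return next(e.rank for e in self.entries if e.name == name)

    def group_of(self, name: str) -> str:
        return next(e.group for e in self.entries if e.name == name)

    def group_members(self, group: str) -> list[str]:
        return [e.name for e in self.by_rank() if e.group == group]

    def non_media(self) -> list[str]:
        return [e.name for e in self.by_rank() if e.group != "media"]

    def monotone_missing_rates(self) -> np.ndarray:
        """Rank-ordered missing-rate targets made feasible for rank truncation.

        A rank-truncation missingness mechanism (a child contributes the first
        ``count`` stimuli in rank order) can only realize rates that are
        non-decreasing in rank.  The published per-stimulus targets are not
        perfectly monotone, so the nearest monotone rates (isotonic
        regression, pool-adjacent-violators) are used to derive the
        available-count distribution.
        """
        rates = np.array([e.target_missing_rate for e in self.by_rank()])
        return _pava_nondecreasing(rates)

    def count_distribution(self) -> np.ndarray:
        """P(available-stimulus count = k) for k = 0..n, from the rate targets.

        ``P(count >= rank r) = 1 - missing_rate(r)`` under rank truncation.
        """
        m = self.monotone_missing_rates()
        n = len(m)
        p = np.empty(n + 1)
        p[0] = m[0]
        p[1:n] = np.diff(m)
        p[n] = 1.0 - m[-1]
        p = np.clip(p, 0.0, None)
        return p / p.sum()


def _pava_nondecreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators isotonic fit (non-decreasing, equal weights)."""
    values = list(map(float, y))
    blocks: list[list[float]] = []  # [mean, weight]
    for v in values:
        blocks.append([v, 1.0])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            m2, w2 = blocks.pop()
            m1, w1 = blocks.pop()
            blocks.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    out: list[float] = []
    for m, w in blocks:
        out.extend([m] * int(round(w)))
    return np.array(out)


@dataclass(frozen=True)
class CytokineEntry:
    name: str
    functional_group: str
    lod_by_batch: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CytokinePanel:
    entries: tuple[CytokineEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("cytokine names must be unique")
        for e in self.entries:
            if e.functional_group not in CYTOKINE_GROUPS:
                raise ValueError(f"unknown functional group {e.functional_group!r}")
            for lod in e.lod_by_batch.values():
                if lod <= 0:
                    raise ValueError("every LOD must be > 0")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def group_of(self, name: str) -> str:
        return next(e.functional_group for e in self.entries if e.name == name)

    def group_members(self, group: str) -> list[str]:
        return [e.name for e in self.entries if e.functional_group == group]

    def lod(self, name: str, batch: int) -> float:
        return next(e.lod_by_batch[batch] for e in self.entries if e.name == name)

    def lod_matrix(self, batch: int) -> np.ndarray:
        return np.array([e.lod_by_batch[batch] for e in self.entries])


# Published stimulus rank order with mean % missing (last column of the
# stimulus table).  polyIC has no printed rate (it was later excluded as
# endotoxin-contaminated); its target is interpolated as the midpoint of its
# rank neighbours RV1B (5.8) and LPS (13.4).
_STIMULI = [
    # (name, group, mean % missing)
    (MEDIA, "media", 0.7),
    ("RV16", "viral", 0.8),
    ("RSV", "viral", 1.3),
    ("Hin", "bacterial", 2.2),
    ("Strpn", "bacterial", 2.9),
    ("PHA", "tcell", 5.1),
    ("RV1B", "viral", 5.8),
    ("polyIC", "viral", 9.6),
    ("LPS", "bacterial", 13.4),
    ("R848", "viral", 17.8),
    ("CpGA", "viral", 32.7),
    ("PAM", "bacterial", 27.8),
    ("PGN", "bacterial", 33.1),
    ("FSL", "bacterial", 37.3),
    ("Fla", "bacterial", 44.5),
    ("LTA", "bacterial", 48.8),
]

# 28-cytokine panel.  The 19 cytokines assigned to the anti-viral,
# pro-inflammatory and T-cell clusters are named in the study narrative; of
# the 9 weak/not-induced cytokines, 7 are named (IFNb, IL15, IL29, IL18,
# IL16, CCL26, CCL17) and two (IL7, GMCSF) are synthetic stand-ins completing
# the panel to 28 for simulation purposes.
_CYTOKINES = [
    # anti-viral / IFN-induced
    ("IFNa2", "anti_viral"),
    ("CXCL10", "anti_viral"),
    ("CCL2", "anti_viral"),
    ("CCL11", "anti_viral"),
    ("CCL13", "anti_viral"),
    # pro-inflammatory (+ IL-10 and CCL22 which co-cluster with them)
    ("IL1b", "pro_inflammatory"),
    ("IL6", "pro_inflammatory"),
    ("CXCL8", "pro_inflammatory"),
    ("CCL4", "pro_inflammatory"),
    ("TNF", "pro_inflammatory"),
    ("IL10", "pro_inflammatory"),
    ("CCL22", "pro_inflammatory"),
    # T-cell derived (+ IL-12p70)
    ("IL12p70", "t_cell"),
    ("IL17", "t_cell"),
    ("IFNg", "t_cell"),
    ("IL2", "t_cell"),
    ("IL4", "t_cell"),
    ("IL5", "t_cell"),
    ("IL13", "t_cell"),
    # weak / not induced
    ("IFNb", "weak"),
    ("IL15", "weak"),
    ("IL29", "weak"),
    ("IL18", "weak"),
    ("IL16", "weak"),
    ("CCL26", "weak"),
    ("CCL17", "weak"),
    ("IL7", "weak"),
    ("GMCSF", "weak"),
]

DEFAULT_LOD = {1: 0.6, 2: 0.3}  # pg/mL; batch 1 assay slightly less sensitive


def default_stimulus_panel() -> StimulusPanel:
    entries = tuple(
        StimulusEntry(name, group, rank, pct / 100.0)
        for rank, (name, group, pct) in enumerate(_STIMULI, start=1)
    )
    return StimulusPanel(entries)


def default_cytokine_panel(lod_by_batch: dict[int, float] | None = None) -> CytokinePanel:
    lods = dict(DEFAULT_LOD if lod_by_batch is None else lod_by_batch)
    entries = tuple(
        CytokineEntry(name, group, dict(lods)) for name, group in _CYTOKINES
    )
    return CytokinePanel(entries)


VIRAL_CORRELATED_FOUR = ("R848", "RV16", "RSV", "CpGA")
PROINFLAMMATORY_EIGHT = ("IL6", "IL1b", "CXCL8", "CCL4", "TNF", "IL17", "CCL2", "CCL13")
VIRUS_INDUCED_FOUR = ("IFNa2", "CXCL10", "CCL11", "CCL2")


def default_specificity_groups(
    stimulus_panel: StimulusPanel | None = None,
    index_stimulus: str = "Hin",
) -> dict[str, list[tuple[str, str]]]:
    """Six (cytokine, stimulus) pair groups used to profile cQTL specificity.

    Sizes under the default panels: IL-6 x other bacterial (7), IL-6 x viral
    (4), pro-inflammatory x bacterial (56), virus-induced x viral (16),
    pro-inflammatory x PHA (7), virus-induced x PHA (4).  ``index_stimulus``
    is the bacterial stimulus the SNP was discovered with and is excluded
    from group 1.
    """
    panel = stimulus_panel or default_stimulus_panel()
    bacterial = panel.group_members("bacterial")
    proinf_non_il6 = [c for c in PROINFLAMMATORY_EIGHT if c != "IL6"]
    return {
        "il6_bacterial_other": [("IL6", s) for s in bacterial if s != index_stimulus],
        "il6_viral": [("IL6", s) for s in VIRAL_CORRELATED_FOUR],
        "proinflammatory_bacterial": [
            (c, s) for c in proinf_non_il6 for s in bacterial
        ],
        "virus_induced_viral": [
            (c, s) for c in VIRUS_INDUCED_FOUR for s in VIRAL_CORRELATED_FOUR
        ],
        "proinflammatory_pha": [(c, "PHA") for c in proinf_non_il6],
        "virus_induced_pha": [(c, "PHA") for c in VIRUS_INDUCED_FOUR],
    }
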