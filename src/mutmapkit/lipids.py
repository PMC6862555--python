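"""Glycerolipid acyl-chain decomposition and the 18:3/18:2 ratio.

Lipidomics facilities report species as ``class C:D`` — total acyl carbons and
total double bonds. For 36-carbon diacyl species the two chains are both
18-carbon and the double bonds are split as evenly as the 18:3/18:2/18:1/18:0
inventory allows (36:6 = di-18:3, 36:5 = 18:3 + 18:2, 36:4 = di-18:2, 36:3 =
18:2 + 18:1 rather than 18:3 + 18:0); 34-carbon species decompose as 16:0 +
18:D, since 16-carbon chains here carry no double bonds (16:3 is not
detectable in this system). Single-chain (lyso) labels of 16 or 18 carbons
are decomposed directly under the same <= 3 double-bond cap.

The omega-3 ratio is the molar-percent-weighted count of 18:3 chains over
18:2 chains across all decomposable species in a profile — the species-level
analogue of the linolenic/linoleic acid ratio.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_SPECIES_RE = re.compile(r"^(\d+):(\d+)$")


@dataclass(frozen=True)
class AcylComposition:
    """One or two acyl chains as (carbons, double_bonds) tuples."""

    chains: tuple[tuple[int, int], ...]

    def count(self, carbons: int, double_bonds: int) -> int:
        return sum(1 for c in self.chains if c == (carbons, double_bonds))


class UndecomposableSpecies(ValueError):
    pass


def parse_species(species: str) -> tuple[int, int]:
    m = _SPECIES_RE.match(species.strip())
    if not m:
        raise ValueError(f"species label {species!r} is not of the form 'C:D'")
    return int(m.group(1)), int(m.group(2))


def decompose_species(species: str) -> AcylComposition:
    """Split a ``C:D`` species label into acyl chains.

    Raises :class:`UndecomposableSpecies` for carbon numbers outside the
    supported 16/18 (single chain) and 34/36 (diacyl) classes, or double-bond
    counts the chain inventory cannot carry.
    """
    carbons, bonds = parse_species(species)
    if bonds < 0:
        raise UndecomposableSpecies(f"{species}: negative double bonds")
    if carbons == 36:
        if bonds > 6:
            raise UndecomposableSpecies(f"{species}: >3 double bonds per 18C chain")
        high = (bonds + 1) // 2
        return AcylComposition(((18, high), (18, bonds - high)))
    if carbons == 34:
        if bonds > 3:
            raise UndecomposableSpecies(
                f"{species}: 16C chains are saturated here, 18C carries <= 3"
            )
        return AcylComposition(((16, 0), (18, bonds)))
    if carbons == 18:
        if bonds > 3:
            raise UndecomposableSpecies(f"{species}: 18C chain carries <= 3 bonds")
        return AcylComposition(((18, bonds),))
    if carbons == 16:
        if bonds != 0:
            raise UndecomposableSpecies(f"{species}: 16C chains are saturated here")
        return AcylComposition(((16, 0),))
    raise UndecomposableSpecies(f"{species}: unsupported carbon number {carbons}")


class LipidProfile:
    """Species-level molar percentages of one sample.

    ``data`` maps (lipid_class, species) -> molar percent. Per-sample molar
    percentages are expected to sum to 100 +/- 0.5 when a profile represents a
    complete sample; partial profiles can skip the check.
    """

    def __init__(
        self,
        data: Mapping[tuple[str, str], float],
        *,
        sample: str = "",
        check_total: bool = True,
    ) -> None:
        for (_, species), pct in data.items():
            parse_species(species)
            if pct < 0:
                raise ValueError(f"negative molar percent for {species}")
        total = sum(data.values())
        if check_total and abs(total - 100.0) > 0.5:
            raise ValueError(f"molar percentages sum to {total:.2f}, expected 100 +/- 0.5")
        self.data = dict(data)
        self.sample = sample

    @classmethod
    def from_species_percent(
        cls, species_percent: Mapping[str, float], *, lipid_class: str = "MGDG", **kw
    ) -> "LipidProfile":
        return cls({(lipid_class, sp): v for sp, v in species_percent.items()}, **kw)

    def items(self):
        return self.data.items()

    def species_universe(self) -> set[tuple[str, str]]:
        return set(self.data)


def chain_totals(profile: LipidProfile) -> tuple[float, float, int]:
    """(weighted 18:3 chains, weighted 18:2 chains, n undecomposable species)."""
    total_183 = total_182 = 0.0
    n_bad = 0
    for (_, species), pct in profile.items():
        try:
            comp = decompose_species(species)
        except UndecomposableSpecies:
            n_bad += 1
            continue
        total_183 += pct * comp.count(18, 3)
        total_182 += pct * comp.count(18, 2)
    if n_bad:
        logger.info("%s: %d species could not be decomposed", profile.sample or "profile", n_bad)
    return total_183, total_182, n_bad


def omega3_ratio(profile: LipidProfile) -> float:
    """Linolenic/linoleic (18:3/18:2) chain ratio over all decomposable species."""
    total_183, total_182, _ = chain_totals(profile)
    if total_182 == 0.0:
        raise ValueError("profile carries no 18:2 chains; the ratio is undefined")
    return total_183 / total_182


def compare_profiles(
    profile_wt: LipidProfile, profile_mut: LipidProfile
) -> pd.DataFrame:
    """Per-species molar-percent deltas (mut - WT) plus the two omega-3 ratios.

    Returns a table with one row per species and a ``ratio`` column holding
    each profile's 18:3/18:2 ratio on the two summary rows.
    """
    universe_wt = profile_wt.species_universe()
    universe_mut = profile_mut.species_universe()
    if not universe_wt & universe_mut:
        raise ValueError("profiles share no species; nothing to compare")
    rows = []
    for key in sorted(universe_wt | universe_mut):
        wt = profile_wt.data.get(key, 0.0)
        mut = profile_mut.data.get(key, 0.0)
        rows.append(
            {
                "lipid_class": key[0], "species": key[1],
                "wt_molar_percent": wt, "mut_molar_percent": mut,
                "delta": mut - wt,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["ratio_wt"] = omega3_ratio(profile_wt)
    df.attrs["ratio_mut"] = omega3_ratio(profile_mut)
    return df


def read_profiles_csv(path: str | Path, *, check_total: bool = True) -> dict[str, LipidProfile]:
    """CSV with columns sample, class, species, molar_percent -> per-sample profiles."""
    df = pd.read_csv(path)
    missing = {"sample", "class", "species", "molar_percent"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles = {}
    for sample, sub in df.groupby("sample"):
        data = {
            (str(r["class"]), str(r["species"])): float(r["molar_percent"])
            for _, r in sub.iterrows()
        }
        profiles[str(sample)] = LipidProfile(data, sample=str(sample), check_total=check_total)
    return profiles
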