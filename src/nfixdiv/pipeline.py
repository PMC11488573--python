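"""Per-plot change statistics and per-species fates from paired surveys.

The raw input is a long-format occurrence table: each plot was censused
twice (a baseline survey and the most recent resurvey, decades apart) and
each row records one species seen in one survey.  From these, with a
genus-level N-fixer trait table and a dated phylogeny, the pipeline
derives:

* per-plot responses — change in the N-fixer proportion of species
  richness, change in N-fixer Faith's PD, and change in the N-fixer
  proportion of total Faith's PD (plus MPD/MNTD variants);
* per-plot guild partitions of the N-fixers — species lost (baseline
  only), gained (resurvey only) or conserved (both);
* per-species fate statistics — counts of plots where the species was
  conserved/lost/gained, the loss and gain probabilities, and the net
  change dP = (PG - PL) / (PC + PG + PL) in [-1, 1].

Plot filters mirror the analysis designs: richness models keep plots with
at least one N-fixer in either survey; distance-based (PD) models need at
least two fixers in one survey; a strict variant requires two in both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import faith_pd, pd_summary
from .environment import EnvChange
from .trees import Phylogeny, TaxonRecord, normalize_label

__all__ = [
    "SurveyPair",
    "GuildPartition",
    "classify_guilds",
    "fixer_proportion",
    "delta_pd_proportion",
    "species_fates",
    "build_change_table",
    "guild_pd_table",
    "read_community_csv",
    "FILTERS",
]

FILTERS = ("richness", "pd", "strict")

GUILDS = ("lost", "gained", "conserved")


@dataclass(frozen=True)
class SurveyPair:
    """One plot's baseline and resurvey species sets."""

    plot: str
    site: str
    baseline_year: int
    resurvey_year: int
    baseline_species: frozenset[str]
    resurvey_species: frozenset[str]

    def __post_init__(self):
        if self.baseline_year >= self.resurvey_year:
            raise ValueError(
                f"plot {self.plot}: baseline year must precede resurvey year"
            )
        if not self.baseline_species or not self.resurvey_species:
            raise ValueError(f"plot {self.plot}: empty species set")


@dataclass(frozen=True)
class GuildPartition:
    """Per-plot partition of N-fixer species by presence pattern."""

    plot: str
    site: str
    lost: frozenset[str]
    gained: frozenset[str]
    conserved: frozenset[str]


def _fixer_lookup(traits: list[TaxonRecord]) -> dict[str, bool]:
    return {r.species: r.is_fixer for r in traits}


def _check_known(species, lookup, context: str) -> None:
    unknown = sorted(s for s in species if s not in lookup)
    if unknown:
        raise KeyError(f"{context}: species missing from trait table: {unknown}")


def classify_guilds(pair: SurveyPair, traits: list[TaxonRecord]) -> GuildPartition:
    """Split a plot's N-fixers into lost / gained / conserved guilds.

    Lost = fixers present at baseline but absent at resurvey; gained =
    present only at resurvey; conserved = present in both.
    """
    lookup = _fixer_lookup(traits)
    allsp = pair.baseline_species | pair.resurvey_species
    _check_known(allsp, lookup, f"plot {pair.plot}")
    base_fix = {s for s in pair.baseline_species if lookup[s]}
    res_fix = {s for s in pair.resurvey_species if lookup[s]}
    return GuildPartition(
        plot=pair.plot,
        site=pair.site,
        lost=frozenset(base_fix - res_fix),
        gained=frozenset(res_fix - base_fix),
        conserved=frozenset(base_fix & res_fix),
    )


def fixer_proportion(species, traits: list[TaxonRecord]) -> float:
    """N-fixer share of species richness: n_fixers / n_species."""
    species = {normalize_label(s) for s in species}
    if not species:
        raise ValueError("empty species set")
    lookup = _fixer_lookup(traits)
    _check_known(species, lookup, "fixer_proportion")
    return sum(lookup[s] for s in species) / len(species)


def _fixer_pd(tree: Phylogeny, fixers) -> float:
    """Faith's PD of a fixer set, 0 for an empty set (all fixers vanished)."""
    return faith_pd(tree, fixers) if fixers else 0.0


def delta_pd_proportion(
    pair: SurveyPair, traits: list[TaxonRecord], tree: Phylogeny
) -> float:
    """Change in the N-fixer share of total Faith's PD between surveys.

    (PD_fixer / PD_all) at resurvey minus the same ratio at baseline.
    """
    lookup = _fixer_lookup(traits)
    _check_known(pair.baseline_species | pair.resurvey_species, lookup, pair.plot)

    def ratio(species):
        total = faith_pd(tree, species)
        if total <= 0:
            raise ValueError(f"plot {pair.plot}: total PD is not positive")
        return _fixer_pd(tree, {s for s in species if lookup[s]}) / total

    return ratio(pair.resurvey_species) - ratio(pair.baseline_species)


def species_fates(
    partitions: list[GuildPartition], *, denominator: str = "occupied"
) -> pd.DataFrame:
    """Aggregate guild partitions into per-species fate statistics.

    For each N-fixer species, counts the plots where it was conserved
    (``PC``), lost (``PL``) and gained (``PG``), and derives:

    * ``p_lost``, ``p_gained`` — loss/gain probabilities.  With
      ``denominator="occupied"`` (default) both use PC + PL + PG, the
      plots where the species occurred in at least one survey; with
      ``denominator="baseline"`` the probabilities condition on presence
      in the relevant survey (PL / (PC + PL), PG / (PC + PG)).
    * ``delta_p`` — net change (PG - PL) / (PC + PG + PL) in [-1, 1].

    Species never observed in any plot simply do not appear.
    """
    if not partitions:
        raise ValueError("need at least one plot")
    if denominator not in ("occupied", "baseline"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    counts: dict[str, dict[str, int]] = {}
    for part in partitions:
        for guild in GUILDS:
            for sp in getattr(part, guild):
                row = counts.setdefault(sp, {"PC": 0, "PL": 0, "PG": 0})
                row["P" + guild[0].upper()] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").rename_axis("species")
    out = out[["PC", "PL", "PG"]].sort_index()
    occ = out.sum(axis=1)
    if denominator == "occupied":
        out["p_lost"] = out["PL"] / occ
        out["p_gained"] = out["PG"] / occ
    else:
        base = out["PC"] + out["PL"]
        res = out["PC"] + out["PG"]
        out["p_lost"] = np.where(base > 0, out["PL"] / base.replace(0, 1), 0.0)
        out["p_gained"] = np.where(res > 0, out["PG"] / res.replace(0, 1), 0.0)
    out["delta_p"] = (out["PG"] - out["PL"]) / occ
    return out.reset_index()


def _passes_filter(n_base_fix: int, n_res_fix: int, variant: str) -> bool:
    if variant == "richness":
        return n_base_fix >= 1 or n_res_fix >= 1
    if variant == "pd":
        return n_base_fix >= 2 or n_res_fix >= 2
    if variant == "strict":
        return n_base_fix >= 2 and n_res_fix >= 2
    raise ValueError(f"unknown filter variant {variant!r}; choose from {FILTERS}")


def build_change_table(
    pairs: list[SurveyPair],
    traits: list[TaxonRecord],
    tree: Phylogeny,
    env_changes: dict[str, EnvChange] | list[EnvChange],
    *,
    filter_variant: str = "pd",
    canopy_change: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the per-plot response/predictor table for the mixed models.

    One row per plot passing `filter_variant` (see module docstring), with
    the three responses as changes (resurvey minus baseline), their
    baseline values (regression-to-the-mean covariates), the site-level
    environmental predictors, and MPD/MNTD under the single-fixer = 0
    convention.

    Raises if any plot's site lacks an environmental change record.
    """
    if isinstance(env_changes, list):
        env_changes = {e.site: e for e in env_changes}
    missing_sites = sorted({p.site for p in pairs} - set(env_changes))
    if missing_sites:
        raise KeyError(f"no environmental change for sites: {missing_sites}")
    lookup = _fixer_lookup(traits)
    rows = []
    for pair in pairs:
        _check_known(
            pair.baseline_species | pair.resurvey_species, lookup, pair.plot
        )
        base_fix = {s for s in pair.baseline_species if lookup[s]}
        res_fix = {s for s in pair.resurvey_species if lookup[s]}
        if not _passes_filter(len(base_fix), len(res_fix), filter_variant):
            continue

        def survey_stats(species, fixers):
            total_pd = faith_pd(tree, species)
            prop_rich = len(fixers) / len(species)
            fix = pd_summary(tree, fixers, singleton_zero=True) if fixers else None
            fix_pd = fix.faith_pd if fix else 0.0
            return {
                "prop_rich": prop_rich,
                "pd": fix_pd,
                "prop_pd": fix_pd / total_pd,
                "mpd": fix.mpd if fix else 0.0,
                "mntd": fix.mntd if fix else 0.0,
            }

        b = survey_stats(pair.baseline_species, base_fix)
        r = survey_stats(pair.resurvey_species, res_fix)
        env = env_changes[pair.site]
        row = {
            "plot": pair.plot,
            "site": pair.site,
            "baseline_year": pair.baseline_year,
            "resurvey_year": pair.resurvey_year,
            "n_fixers_baseline": len(base_fix),
            "n_fixers_resurvey": len(res_fix),
            "delta_prop_rich": r["prop_rich"] - b["prop_rich"],
            "delta_pd": r["pd"] - b["pd"],
            "delta_prop_pd": r["prop_pd"] - b["prop_pd"],
            "delta_mpd": r["mpd"] - b["mpd"],
            "delta_mntd": r["mntd"] - b["mntd"],
            "baseline_prop_rich": b["prop_rich"],
            "baseline_pd": b["pd"],
            "baseline_prop_pd": b["prop_pd"],
            "baseline_mpd": b["mpd"],
            "baseline_mntd": b["mntd"],
            "cum_n": env.cum_n,
            "delta_t": env.delta_t,
            "delta_ai": env.delta_ai,
        }
        if canopy_change is not None:
            if pair.plot not in canopy_change:
                raise KeyError(f"no canopy change for plot {pair.plot}")
            row["delta_canopy"] = canopy_change[pair.plot]
        rows.append(row)
    return pd.DataFrame(rows)


def guild_pd_table(
    partitions: list[GuildPartition], tree: Phylogeny
) -> pd.DataFrame:
    """Per-plot, per-guild diversity metrics for the guild comparisons.

    Emits one row per (plot, guild) with a non-empty guild: Faith's PD,
    MPD and MNTD (singletons report MPD = MNTD = 0) and the guild size.
    """
    rows = []
    for part in partitions:
        for guild in GUILDS:
            members = getattr(part, guild)
            if not members:
                continue
            res = pd_summary(tree, members, singleton_zero=True)
            rows.append(
                {
                    "plot": part.plot,
                    "site": part.site,
                    "guild": guild,
                    "faith_pd": res.faith_pd,
                    "mpd": res.mpd,
                    "mntd": res.mntd,
                    "n_species": res.n_taxa,
                }
            )
    return pd.DataFrame(rows)


_LOW_RES = re.compile(r"^(sp{1,2}\.?|spec\.?|sp\d*|indet\.?|cf\.?)$", re.IGNORECASE)


def is_low_resolution(species: str) -> bool:
    """True for genus-or-coarser identifications such as ``Lathyrus_sp``."""
    parts = normalize_label(species).split("_")
    return len(parts) < 2 or bool(_LOW_RES.match(parts[1]))


def read_community_csv(
    path, *, drop_low_resolution: bool = False
) -> list[SurveyPair]:
    """Read the long-format community table into survey pairs.

    Expected columns: ``plot, site, survey_role, year, species`` with
    ``survey_role`` in {baseline, resurvey}; an optional ``cover`` column
    is ignored (analyses are presence-based).  If a plot has several
    resurveys only the most recent is kept.  With
    ``drop_low_resolution=True``, genus-or-coarser identifications are
    removed (they are kept by default; most are genera with no congeners
    in the survey, which barely move the metrics).
    """
    df = pd.read_csv(path)
    required = {"plot", "site", "survey_role", "year", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"community table missing columns: {sorted(missing)}")
    bad = set(df["survey_role"].unique()) - {"baseline", "resurvey"}
    if bad:
        raise ValueError(f"survey_role must be baseline|resurvey, got {sorted(bad)}")
    df = df.copy()
    df["species"] = df["species"].map(normalize_label)
    df["plot"] = df["plot"].astype(str)
    df["site"] = df["site"].astype(str)
    df["year"] = df["year"].astype(int)
    if drop_low_resolution:
        df = df[~df["species"].map(is_low_resolution)]
    pairs = []
    for plot, grp in df.groupby("plot", sort=True):
        base = grp[grp["survey_role"] == "baseline"]
        res = grp[grp["survey_role"] == "resurvey"]
        if base.empty or res.empty:
            raise ValueError(f"plot {plot}: needs both a baseline and a resurvey")
        if base["year"].nunique() > 1:
            raise ValueError(f"plot {plot}: multiple baseline years")
        res = res[res["year"] == res["year"].max()]  # keep most recent resurvey
        sites = grp["site"].unique()
        if len(sites) != 1:
            raise ValueError(f"plot {plot}: inconsistent site labels {sites.tolist()}")
        pairs.append(
            SurveyPair(
                plot=plot,
                site=sites[0],
                baseline_year=int(base["year"].iloc[0]),
                resurvey_year=int(res["year"].iloc[0]),
                baseline_species=frozenset(base["species"]),
                resurvey_species=frozenset(res["species"]),
            )
        )
    return pairs

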