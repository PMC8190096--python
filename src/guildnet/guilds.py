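"""FUNGuild-style guild assignment of fungal taxa.

Taxon lineages (rank-prefixed, semicolon-delimited: ``k__Fungi;...;g__Fusarium``)
are matched against a curated trait database at the most specific shared rank,
then the matched record's guild string is classified into one of five classes:

* ``AMF`` — arbuscular mycorrhizal fungi (putative mutualists); only accepted
  at Highly Probable / Probable confidence,
* ``PATHOGEN`` — plant pathogens,
* ``SAPROTROPH`` — soil or undefined saprotrophs (wood/dung/litter specialists
  are deliberately excluded as non-representative substrates),
* ``OTHER`` — any other database match,
* ``UNASSIGNED`` — no database match.

Every taxon receives exactly one class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from ._exceptions import ConsistencyError, LineageParseError

logger = logging.getLogger(__name__)

# guild classes
AMF = "AMF"
PATHOGEN = "PATHOGEN"
SAPROTROPH = "SAPROTROPH"
OTHER = "OTHER"
UNASSIGNED = "UNASSIGNED"
GUILD_CLASSES = (AMF, PATHOGEN, SAPROTROPH, OTHER, UNASSIGNED)
#: classes counted in guild abundance analyses
TARGET_CLASSES = (AMF, PATHOGEN, SAPROTROPH)

CONFIDENCE_LEVELS = ("Highly Probable", "Probable", "Possible")
#: AMF assignments below this confidence are demoted to OTHER
AMF_CONFIDENCE = frozenset({"Highly Probable", "Probable"})

RANK_PREFIXES = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
#: most specific first, for database matching
MATCH_RANK_ORDER = ("species", "genus", "family", "order", "class", "phylum", "kingdom")

SAPROTROPH_TERMS = ("Soil Saprotroph", "Undefined Saprotroph")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a rank-prefixed lineage string into a ``{rank: name}`` map.

    Empty names (``s__``) are omitted; an unknown rank prefix raises
    :class:`LineageParseError` naming the offending token.
    """
    out: dict[str, str] = {}
    if not lineage or not lineage.strip():
        return out
    for token in lineage.split(";"):
        token = token.strip()
        if not token:
            continue
        prefix, sep, name = token.partition("__")
        if not sep or prefix not in RANK_PREFIXES:
            raise LineageParseError(f"malformed lineage token: {token!r}")
        name = name.strip()
        if name:
            out[RANK_PREFIXES[prefix]] = name
    return out


@dataclass
class GuildDatabase:
    """FUNGuild-like trait database.

    ``records`` columns: ``taxon`` (name at the given rank), ``taxonomicLevel``
    (rank name, e.g. ``genus``/``family``), ``trophicMode``, ``guild``,
    ``confidenceRanking``.
    """

    records: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("taxon", "taxonomicLevel", "trophicMode", "guild", "confidenceRanking")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"guild database missing columns: {missing}")
        bad_conf = set(self.records["confidenceRanking"]) - set(CONFIDENCE_LEVELS)
        if bad_conf:
            raise ValueError(f"unknown confidence rankings: {sorted(bad_conf)}")
        key = self.records["taxonomicLevel"].str.lower() + "|" + self.records["taxon"].str.lower()
        if key.duplicated().any():
            dupes = self.records.loc[key.duplicated(), "taxon"].tolist()
            raise ValueError(f"duplicate database names at a level: {dupes}")
        # case-insensitive lookup: (level, lower-cased name) -> row
        self._index = {
            (lvl.lower(), name.lower()): row
            for (lvl, name), row in zip(
                zip(self.records["taxonomicLevel"], self.records["taxon"]),
                self.records.to_dict("records"),
            )
        }

    def lookup(self, level: str, name: str) -> dict | None:
        return self._index.get((level.lower(), name.lower()))

    @classmethod
    def from_tsv(cls, path) -> "GuildDatabase":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def classify_guild_record(guild: str, trophic_mode: str, confidence: str) -> str:
    """Map a matched database record to a guild class.

    Multi-guild strings resolve by priority AMF > PATHOGEN > SAPROTROPH
    (logged as ambiguous); the confidence filter applies to AMF only.
    """
    guild = guild or ""
    trophic_mode = trophic_mode or ""
    hits = []
    if "Arbuscular Mycorrhizal" in guild and confidence in AMF_CONFIDENCE:
        hits.append(AMF)
    if "Plant Pathogen" in guild:
        hits.append(PATHOGEN)
    if any(t in guild or t in trophic_mode for t in SAPROTROPH_TERMS):
        hits.append(SAPROTROPH)
    if len(hits) > 1:
        logger.debug("ambiguous guild string %r -> %s by priority", guild, hits[0])
    return hits[0] if hits else OTHER


class GuildAssigner(BaseEstimator):
    """Assign guild classes to taxa by database lookup at the most specific rank.

    Follows the sklearn estimator protocol: :meth:`fit` takes the database,
    :meth:`assign` maps a taxonomy table (``taxon_id``, ``lineage``) to
    per-taxon assignments.

    Parameters
    ----------
    amf_confidence : frozenset of str
        Confidence rankings accepted for the AMF class.
    """

    def __init__(self, amf_confidence: frozenset = AMF_CONFIDENCE):
        self.amf_confidence = amf_confidence

    def fit(self, db: GuildDatabase, y=None) -> "GuildAssigner":
        if not isinstance(db, GuildDatabase):
            db = GuildDatabase(db)
        self.db_ = db
        return self

    def assign_one(self, lineage: str) -> dict:
        """Assignment record for a single lineage string."""
        ranks = parse_lineage(lineage)
        for rank in MATCH_RANK_ORDER:
            name = ranks.get(rank)
            if name is None:
                continue
            rec = self.db_.lookup(rank, name)
            if rec is not None:
                conf = rec["confidenceRanking"]
                guild = rec["guild"]
                cls = classify_guild_record(guild, rec["trophicMode"], conf)
                if cls == AMF and conf not in self.amf_confidence:
                    cls = OTHER
                return {
                    "guild_class": cls,
                    "matched_level": rank,
                    "confidence": conf,
                    "raw_guild": guild,
                    "genus": ranks.get("genus", ""),
                }
        return {
            "guild_class": UNASSIGNED,
            "matched_level": "",
            "confidence": "",
            "raw_guild": "",
            "genus": ranks.get("genus", ""),
        }

    def assign(self, taxonomy: pd.DataFrame) -> pd.DataFrame:
        """Per-taxon assignments for a taxonomy table (taxon_id, lineage)."""
        rows = []
        for taxon_id, lineage in zip(taxonomy["taxon_id"], taxonomy["lineage"]):
            rec = self.assign_one(lineage)
            rec["taxon_id"] = taxon_id
            rows.append(rec)
        cols = ["taxon_id", "guild_class", "matched_level", "confidence", "raw_guild", "genus"]
        return pd.DataFrame(rows, columns=cols)


def assign_guilds(taxonomy: pd.DataFrame, db: GuildDatabase) -> pd.DataFrame:
    """Functional wrapper over :class:`GuildAssigner`."""
    return GuildAssigner().fit(db).assign(taxonomy)


def assignment_summary(assignments: pd.DataFrame, counts: pd.DataFrame) -> pd.Series:
    """Fraction of total reads per guild class.

    ``counts`` is taxa x plots; every taxon in ``counts`` must appear in
    ``assignments``. Fractions sum to 1 across all five classes.
    """
    cls = assignments.set_index("taxon_id")["guild_class"]
    missing = counts.index.difference(cls.index)
    if len(missing):
        raise ConsistencyError(f"taxa in counts without assignments: {list(missing)[:5]}")
    total = counts.to_numpy().sum()
    reads = counts.sum(axis=1).groupby(cls.reindex(counts.index)).sum()
    frac = reads.reindex(GUILD_CLASSES, fill_value=0).astype(float) / total
    frac.index.name = "guild_class"
    return frac


def read_assignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index=False)
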