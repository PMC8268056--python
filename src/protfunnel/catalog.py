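"""Protease catalog: the gene universe and its subcellular-localization filter.

The prioritization cascade starts from a catalog of every protease in the
genome, annotated with subcellular-localization terms, and keeps only those
accessible outside the cell (extracellular, secreted, or membrane-anchored).
The catalog is a static input table — there is no live annotation lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

#: Controlled vocabulary of localization terms accepted at load time.
CONTROLLED_VOCABULARY = frozenset(
    {
        "extracellular",
        "transmembrane",
        "secreted",
        "plasma_membrane",
        "cytoplasm",
        "nucleus",
        "lysosome",
        "mitochondrion",
        "er_golgi",
        "other",
    }
)

#: Default notion of "extracellular or transmembrane": terms that place a
#: protease (or part of it) outside the plasma membrane. Multi-localized
#: proteases pass if ANY of their terms is allowed, which keeps
#: transmembrane proteases that also have intracellular domains.
DEFAULT_SURFACE_TERMS = frozenset(
    {"extracellular", "transmembrane", "secreted", "plasma_membrane"}
)


class CatalogError(ValueError):
    """Raised for malformed catalog files or invalid filter arguments."""


@dataclass(frozen=True)
class ProteaseCatalog:
    """A protease universe with localization annotations.

    ``entries`` maps uppercased gene symbols to frozensets of localization
    terms drawn from :data:`CONTROLLED_VOCABULARY`. The catalog defines the
    panel over which panel averages and standard deviations are computed.
    """

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for symbol, terms in self.entries.items():
            if symbol != symbol.upper():
                raise CatalogError(f"gene symbol not normalized: {symbol!r}")
            unknown = set(terms) - CONTROLLED_VOCABULARY
            if unknown:
                raise CatalogError(
                    f"unknown localization terms for {symbol}: {sorted(unknown)}"
                )

    @property
    def panel_size(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_protease_catalog(path: str | Path) -> ProteaseCatalog:
    """Load a protease catalog from a tab-separated table.

    Format: header line ``gene_symbol<TAB>localization``, one row per
    protease, localization terms joined by ";". Symbols are uppercased;
    duplicate symbols are merged by union of their terms with a warning.

    Raises
    ------
    CatalogError
        If the file is empty, the header is wrong, a row is malformed, or
        a localization term is outside the controlled vocabulary.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].strip():
        raise CatalogError(f"empty catalog file: {path}")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip() for h in header[:2]] != ["gene_symbol", "localization"]:
        raise CatalogError(
            f"{path}: expected header 'gene_symbol<TAB>localization', got {lines[0]!r}"
        )
    entries: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise CatalogError(f"{path}:{lineno}: malformed row {raw!r}")
        symbol = parts[0].strip().upper()
        terms = frozenset(t.strip() for t in parts[1].split(";") if t.strip())
        unknown = set(terms) - CONTROLLED_VOCABULARY
        if unknown:
            raise CatalogError(
                f"{path}:{lineno}: unknown localization terms {sorted(unknown)}"
            )
        if symbol in entries:
            logger.warning(
                "duplicate catalog symbol %s at line %d; merging terms", symbol, lineno
            )
            terms = entries[symbol] | terms
        entries[symbol] = terms
    if not entries:
        raise CatalogError(f"catalog file has a header but no entries: {path}")
    return ProteaseCatalog(entries=entries)


def filter_by_localization(
    catalog: ProteaseCatalog, allowed: set[str] | frozenset[str]
) -> ProteaseCatalog:
    """Restrict the catalog to proteases with at least one allowed term.

    ``allowed`` must be a non-empty subset of the controlled vocabulary.
    The inclusive any-term rule keeps multi-localized proteases as long as
    one annotation places them at or outside the plasma membrane.
    """
    if not allowed:
        raise CatalogError("allowed localization set must be non-empty")
    unknown = set(allowed) - CONTROLLED_VOCABULARY
    if unknown:
        raise CatalogError(f"allowed set contains unknown terms: {sorted(unknown)}")
    kept = {
        symbol: terms
        for symbol, terms in catalog.entries.items()
        if terms & set(allowed)
    }
    return ProteaseCatalog(entries=kept)


def write_protease_catalog(catalog: ProteaseCatalog, path: str | Path) -> None:
    """Serialize a catalog back to the tab-separated table format."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_symbol\tlocalization\n")
        for symbol, terms in catalog.entries.items():
            fh.write(f"{symbol}\t{';'.join(sorted(terms))}\n")
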