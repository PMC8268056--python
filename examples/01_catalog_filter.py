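"""Restrict a protease catalog to surface-accessible members.

Loads a small annotated catalog and applies the localization filter that
opens the prioritization cascade: only proteases with at least one
extracellular / transmembrane / secreted / plasma-membrane term survive,
because an intracellular protease can never reach a linker-capped
nanoparticle outside the cell.
"""

from pathlib import Path

from protfunnel import DEFAULT_SURFACE_TERMS, filter_by_localization, load_protease_catalog

here = Path(__file__).parent
catalog = load_protease_catalog(here / "data" / "catalog.tsv")
surface = filter_by_localization(catalog, DEFAULT_SURFACE_TERMS)

print(f"catalog: {catalog.panel_size} proteases")
print(f"surface-accessible: {surface.panel_size} proteases")
for symbol, terms in surface.entries.items():
    print(f"  {symbol:8s} {';'.join(sorted(terms))}")
# The survivors define the panel over which all later panel averages and
# standard deviations are computed.
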