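"""The conventional size-ordered module colour palette.

Modules are named by decreasing size through this fixed sequence, so the
largest module is always "turquoise" and unassigned genes are always
"grey".  Beyond the palette, modules fall back to "module<N>".
"""

MODULE_PALETTE: tuple[str, ...] = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
    "lightcyan",
    "grey60",
    "lightgreen",
    "lightyellow",
    "royalblue",
    "darkred",
    "darkgreen",
    "darkturquoise",
    "darkgrey",
    "orange",
    "darkorange",
    "white",
    "skyblue",
    "saddlebrown",
    "steelblue",
    "paleturquoise",
    "violet",
    "darkolivegreen",
    "darkmagenta",
)

GREY = "grey"


def palette_color(rank: int) -> str:
    """Colour for the module of the given size rank (0 = largest)."""
    if rank < len(MODULE_PALETTE):
        return MODULE_PALETTE[rank]
    return f"module{rank + 1}"
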