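{
  "note": "15 phantom comparison colors: ten corner hues of five optimized foreground/background color-map pairs, the standard H-DAB blue and brown, and black/gray/white controls. The hues of map pairs C, D and E are SYNTHETIC stand-ins chosen within the red-orange/blue families the design rules admit; the published source lists only the pairs A and B hues in its figures.",
  "colors": [
    "#FF0000",
    "#0093FF",
    "#006EFF",
    "#FFAD00",
    "#FF6600",
    "#0055C8",
    "#C80000",
    "#00AAFF",
    "#FF9632",
    "#283CB4",
    "#5C5FA1",
    "#B58C70",
    "#000000",
    "#808080",
    "#FFFFFF"
  ],
  "map_pairs": {
    "A": ["#FF0000", "#0093FF"],
    "B": ["#006EFF", "#FFAD00"],
    "C": ["#FF6600", "#0055C8"],
    "D": ["#C80000", "#00AAFF"],
    "E": ["#FF9632", "#283CB4"]
  },
  "controls": ["#5C5FA1", "#B58C70", "#000000", "#808080", "#FFFFFF"]
}
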