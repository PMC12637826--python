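"""Tissue label codes shared across modules."""

BACKGROUND = 0
NORMAL = 1
FIBROSIS = 2
SCAR = 3

LABEL_NAMES = {
    BACKGROUND: "background",
    NORMAL: "normal",
    FIBROSIS: "fibrosis",
    SCAR: "scar",
}
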