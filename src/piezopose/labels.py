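"""The three-class sitting-posture label set, in canonical order."""

POSTURES = ("normal", "slight_hunchback", "severe_hunchback")
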