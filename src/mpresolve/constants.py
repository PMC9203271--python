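"""Physical constants (SI)."""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
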