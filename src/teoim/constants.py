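"""Physical constants (CODATA 2018). All SI."""

SPEED_OF_LIGHT = 299_792_458.0
"""Speed of light in vacuum, m/s."""

VACUUM_PERMITTIVITY = 8.8541878128e-12
"""Vacuum permittivity eps0, F/m."""
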