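"""Physical constants and default coefficient values.

All internal computation uses SI units: kelvin, pascal, metres, kilograms,
relative humidity as a fraction, conductances in m s⁻¹.  Unit conversions
(°C, %, g, cm²) happen only at I/O boundaries.
"""

#: Stefan–Boltzmann constant (W m⁻² K⁻⁴).
STEFAN_BOLTZMANN = 5.670374419e-8

#: Universal gas constant (J mol⁻¹ K⁻¹).
GAS_CONSTANT = 8.3145

#: Molar mass of dry air (kg mol⁻¹), used for the ideal-gas air density.
MOLAR_MASS_AIR = 0.0289647

#: Specific heat capacity of (humid) air, J kg⁻¹ K⁻¹.  Treated as a constant
#: coefficient at lab conditions (~20 °C); overridable via config.
CP_AIR = 1010.0

#: Latent heat of vaporization of water, J kg⁻¹ (20 °C value).
LATENT_HEAT_VAPORIZATION = 2.45e6

#: Ratio of boundary-layer conductance to heat over that to water vapour
#: for laminar flow over a flat leaf: g_bh ≈ 0.92 g_bw.
HEAT_TO_VAPOUR_RATIO = 0.92

#: Ratio of molar masses of water vapour and dry air (Pa → kg m⁻³ conversion
#: factor numerator in the latent-flux term).
EPSILON_WATER_AIR = 0.622

#: Long-wave emissivity of liquid water in the 7.5–14 µm band, the reference
#: emitter of the reference-emittance technique.
WATER_EMISSIVITY = 0.98

#: Standard atmospheric pressure (Pa).
STANDARD_PRESSURE = 101325.0
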