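"""Published lysozyme/nanoparticle reference values used as ground truth.

These are the reported experimental values for lysozyme crystallization
in emulsion droplets with and without functionalized gold nanoparticles
(NHS- and maleimide-bioconjugate surfaces).  The worked examples and the
parameter-recovery studies simulate emulsions whose true rates are set to
these numbers and check that the estimators recover them.
"""

#: Volumetric nucleation rates, mm⁻³ s⁻¹, by nanoparticle condition.
LYSOZYME_NUCLEATION_RATES = {
    "control": 4.4,  # no nanoparticles
    "MAL": 8.2,      # maleimide-functionalized gold nanoparticles
    "NHS": 13.8,     # NHS-ester-functionalized gold nanoparticles
}

#: Reported induction-time reduction factors versus the control.
INDUCTION_TIME_REDUCTION_FACTORS = {"MAL": 4.5, "NHS": 7.5}

#: Reported increases in batch nucleation probability versus control
#: (fractions, at low protein concentration, n = 32 drops per arm).
BATCH_PROBABILITY_INCREASE = {"NHS": 0.20, "MAL": 0.50}

#: Droplet volume used when converting decay slopes to volumetric rates
#: in the reference simulations, mm³ (≈ a 50 μm-radius spherical droplet
#: in a 200 μm monolayer capillary).
REFERENCE_DROPLET_VOLUME_MM3 = 5e-4

#: Imaging cadence: one frame per minute.
REFERENCE_FRAME_INTERVAL_S = 60.0

#: Batch replicates per condition.
BATCH_N_DROPS = 32
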