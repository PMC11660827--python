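"""Extract respiration parameters from a mito-stress OCR trace.

Simulates a Seahorse-style trace (3 cycles per phase, plateaus 100 / 40 /
150 / 20 pmol O2/min, measurement noise sd 2) and extracts non-mitochondrial
respiration, basal respiration, ATP-linked OCR, proton leak and coupling
efficiency.
"""

from txrescue import mito_stress_params, simulate_mito_trace

trace = simulate_mito_trace(
    initial=100.0, min_oligo=40.0, min_rotaa=20.0, fccp=150.0,
    cycles_per_phase=3, noise_sd=2.0, seed=11,
)
print(trace.to_frame().to_string(index=False))

params = mito_stress_params(trace)
print()
for name, value in params.to_dict().items():
    print(f"{name:24s} {value:8.3f}")

# NMOC is the rotenone/antimycin-A floor; basal respiration is everything
# above it before any injection; the oligomycin-insensitive remainder is the
# proton leak; coupling efficiency is the ATP-linked share of pre-injection
# oxygen consumption (0.6 for these plateaus).
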