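"""Complexity profile of the four architecture variants.

Builds the calibrated full-scale models (512x512 input, sequence length 3)
and prints trainable parameters and analytic forward MACs per variant,
plus the exact per-branch budgets implied by their differences.
"""

from trunet.profiling import profile_variants

df = profile_variants(image_size=512, T=3)
print(df[["variant", "params_M", "macs_G"]].to_string(index=False))

p = df.set_index("variant")["params"]
print()
print(f"ConvLSTM branch budget : {(p['TR-Unet (full)'] - p['-ConvLSTM']) / 1e6:.2f} M params")
print(f"CA/fusion stack budget : {(p['TR-Unet (full)'] - p['-CA']) / 1e6:.2f} M params")

# The two budgets are exactly additive: removing a branch removes exactly
# its parameters, so (full - -ConvLSTM) == (-CA - ResUnet) and vice versa.
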