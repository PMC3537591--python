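{
  "name": "qshift-14",
  "description": "14-tap orthonormal quarter-delay (q-shift) low-pass analysis prototype for the later stages of the dual-tree complex wavelet transform; tree B uses the time reverse. Projected onto the exact orthonormality manifold (see scripts/design_qshift_filter.py).",
  "h0": [
    0.003253131213967681,
    -0.003883199718140861,
    0.03466023431105628,
    -0.038872687863661166,
    -0.11720401574997484,
    0.2752954798644812,
    0.7561455341226799,
    0.5688105339884646,
    0.0118659739854676,
    -0.10671168816241258,
    0.023825378650409772,
    0.017025219690120042,
    -0.005439455347058824,
    -0.004556876612303714
  ],
  "max_constraint_residual": 2.220446049250313e-16,
  "energy_centroid_delay": 6.249293304360475
}
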