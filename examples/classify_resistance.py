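"""Four-level lodging-resistance classification, measured vs inferred.

Clusters the Fmax values of a synthetic population into four groups,
derives the force boundaries between resistance levels, classifies
every plant twice (from destructive Fmax and from nondestructive F45),
and reports the per-level agreement.
"""

from stalkpull import (
    PAPER2023_SCHEME,
    accuracy_table,
    classify_population,
    cluster_fmax,
    default_config,
    extract_features,
    fit_inference_line,
    generate_population,
    scheme_from_clusters,
)

traces, _ = generate_population(default_config(seed=1))
features = [extract_features(t) for t in traces]

labels, summary = cluster_fmax([f.Fmax for f in features], k=4)
print("Fmax clusters (weakest to strongest):")
print(summary.to_frame().round(2).to_string())

scheme = scheme_from_clusters(summary)
print(f"\nderived level boundaries: {tuple(round(b, 2) for b in scheme.boundaries)} N "
      f"(field calibration: {PAPER2023_SCHEME.boundaries} N)")

inference = fit_inference_line(
    [(f.F45, f.Fmax) for f in features if f.F45 is not None]
)
measured = classify_population(features, scheme, mode="measured")
inferred = classify_population(features, scheme, inference, mode="inferred")
print("\nper-level agreement of nondestructive vs destructive grading:")
print(accuracy_table(measured, inferred).to_string())
print("\nEach accuracy is the share of plants whose F45-inferred level "
      "matches their measured level; plants broken before 45 deg cannot "
      "be graded nondestructively and are excluded.")
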