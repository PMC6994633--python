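{
  "comment": "Population presets for the synthetic FLIM generator. Anchored values: tau_free_true = 0.45 ns (shared free-NAD(P)H lifetime of the hematopoietic populations) and HSC tau_bound_true = 3.56 ns (baseline of the LDH-inhibition experiment). All other numbers are non-authoritative defaults chosen to encode the qualitative population orderings (HSC: lowest ORR; highest alpha_bound, tau_bound, edge/center enrichment and polarity; Lin-CD45+ lowest tau_bound) at realistic dispersion, not measured values.",
  "anchored_fields": ["tau_free_true", "HSC.tau_bound_true"],
  "populations": {
    "HSC": {
      "mean": {
        "radius": 7.0,
        "alpha_bound_true": 0.78,
        "tau_bound_true": 3.56,
        "tau_free_true": 0.45,
        "total_photons": 8000,
        "orr_true": 0.25,
        "edge_enrichment": 1.6,
        "polarity_offset": 0.15
      },
      "sd": {
        "radius": 0.5,
        "alpha_bound_true": 0.04,
        "tau_bound_true": 0.12,
        "total_photons": 800,
        "orr_true": 0.03,
        "edge_enrichment": 0.12,
        "polarity_offset": 0.03
      }
    },
    "MPP": {
      "mean": {
        "radius": 7.0,
        "alpha_bound_true": 0.65,
        "tau_bound_true": 3.0,
        "tau_free_true": 0.45,
        "total_photons": 8000,
        "orr_true": 0.40,
        "edge_enrichment": 1.5,
        "polarity_offset": 0.06
      },
      "sd": {
        "radius": 0.5,
        "alpha_bound_true": 0.04,
        "tau_bound_true": 0.12,
        "total_photons": 800,
        "orr_true": 0.03,
        "edge_enrichment": 0.12,
        "polarity_offset": 0.02
      }
    },
    "LinNegCD45": {
      "mean": {
        "radius": 7.5,
        "alpha_bound_true": 0.60,
        "tau_bound_true": 2.70,
        "tau_free_true": 0.45,
        "total_photons": 9000,
        "orr_true": 0.50,
        "edge_enrichment": 1.0,
        "polarity_offset": 0.04
      },
      "sd": {
        "radius": 0.6,
        "alpha_bound_true": 0.05,
        "tau_bound_true": 0.15,
        "total_photons": 900,
        "orr_true": 0.05,
        "edge_enrichment": 0.08,
        "polarity_offset": 0.02
      }
    },
    "CD45": {
      "mean": {
        "radius": 7.5,
        "alpha_bound_true": 0.62,
        "tau_bound_true": 2.95,
        "tau_free_true": 0.45,
        "total_photons": 9000,
        "orr_true": 0.48,
        "edge_enrichment": 1.05,
        "polarity_offset": 0.05
      },
      "sd": {
        "radius": 0.6,
        "alpha_bound_true": 0.05,
        "tau_bound_true": 0.15,
        "total_photons": 900,
        "orr_true": 0.05,
        "edge_enrichment": 0.08,
        "polarity_offset": 0.02
      }
    }
  }
}
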