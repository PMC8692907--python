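{
  "type": "object",
  "required": ["tool", "version", "config", "n_images", "n_failed", "failures", "groups", "outputs", "comparisons", "timings", "total_seconds"],
  "properties": {
    "tool": {"type": "string"},
    "version": {"type": "string"},
    "config": {
      "type": "object",
      "required": ["manifest", "output_dir", "binarize_method", "prune_len_um", "stats_level", "seed"]
    },
    "n_images": {"type": "integer"},
    "n_failed": {"type": "integer"},
    "failures": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["image_id", "path", "error"],
        "properties": {
          "image_id": {"type": "string"},
          "path": {"type": "string"},
          "error": {"type": "string"}
        }
      }
    },
    "groups": {"type": "array", "items": {"type": "string"}},
    "outputs": {
      "type": "object",
      "required": ["metrics_csv", "segments_csv"]
    },
    "comparisons": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["parameter", "n_a", "n_b", "mean_a", "mean_b", "sd_a", "sd_b", "p_value", "fold_change", "test", "level"],
        "properties": {
          "parameter": {"type": "string"},
          "n_a": {"type": "integer"},
          "n_b": {"type": "integer"},
          "mean_a": {"type": "number"},
          "mean_b": {"type": "number"},
          "p_value": {"type": "number"},
          "test": {"type": "string"}
        }
      }
    },
    "timings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["image_id", "seconds"]
      }
    },
    "total_seconds": {"type": "number"}
  }
}
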