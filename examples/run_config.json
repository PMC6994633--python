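{
  "seed": 17,
  "acquisition": {"frame_shape": [200, 200]},
  "populations": [
    {"name": "HSC", "n_cells": 30},
    {"name": "LinNegCD45", "n_cells": 30},
    {"name": "CD45", "n_cells": 30}
  ],
  "tau_free": 0.45,
  "band_fraction": 0.3,
  "gate": {"target": "HSC", "features": "all"}
}
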