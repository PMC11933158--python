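{
  "comment": "Mitral-regurgitation orifice phantom catalog: three shapes (circle, slit = pointed oval, drop) in three sizes. h = height (diameter for circle), w = width, both in mm; area_scan_mm2 is the flatbed-scanner-measured area of the laser-cut phantom.",
  "orifices": [
    {"label": "circle-S", "shape": "circle", "h_mm": 4.7,  "area_scan_mm2": 17.1},
    {"label": "circle-M", "shape": "circle", "h_mm": 8.7,  "area_scan_mm2": 58.8},
    {"label": "circle-L", "shape": "circle", "h_mm": 12.2, "area_scan_mm2": 116.7},
    {"label": "slit-S",   "shape": "slit",   "h_mm": 3.3,  "w_mm": 11.1, "area_scan_mm2": 27.0},
    {"label": "slit-M",   "shape": "slit",   "h_mm": 4.5,  "w_mm": 14.0, "area_scan_mm2": 44.8},
    {"label": "slit-L",   "shape": "slit",   "h_mm": 7.3,  "w_mm": 22.9, "area_scan_mm2": 115.1},
    {"label": "drop-S",   "shape": "drop",   "h_mm": 4.3,  "w_mm": 9.7,  "area_scan_mm2": 27.1},
    {"label": "drop-M",   "shape": "drop",   "h_mm": 6.5,  "w_mm": 13.7, "area_scan_mm2": 52.1},
    {"label": "drop-L",   "shape": "drop",   "h_mm": 9.0,  "w_mm": 19.8, "area_scan_mm2": 108.4}
  ]
}
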