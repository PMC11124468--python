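{
  "units": "mm",
  "description": "Mean osteometric dimensions of pediatric lumbar vertebral bodies, five age groups x five lumbar levels x seven dimensions. AVBH/PVBH: anterior/posterior vertebral body height; SVBL/IVBL: superior/inferior vertebral body length (sagittal); SVBW/MVBW/IVBW: superior/middle/inferior vertebral body width (frontal).",
  "groups": [
    {
      "index": 1,
      "label": "newborn (0 yrs)",
      "specimen_count": 23,
      "levels": {
        "L1": {"AVBH": 6.9, "PVBH": 7.2, "SVBL": 7.6, "IVBL": 7.7, "SVBW": 14.5, "MVBW": 15.1, "IVBW": 14.7},
        "L2": {"AVBH": 7.0, "PVBH": 7.2, "SVBL": 7.6, "IVBL": 7.7, "SVBW": 14.6, "MVBW": 15.1, "IVBW": 14.6},
        "L3": {"AVBH": 7.2, "PVBH": 7.2, "SVBL": 7.7, "IVBL": 7.7, "SVBW": 14.6, "MVBW": 15.2, "IVBW": 14.6},
        "L4": {"AVBH": 7.1, "PVBH": 7.3, "SVBL": 7.8, "IVBL": 7.8, "SVBW": 14.8, "MVBW": 15.4, "IVBW": 14.9},
        "L5": {"AVBH": 7.0, "PVBH": 7.3, "SVBL": 7.8, "IVBL": 7.8, "SVBW": 14.8, "MVBW": 15.4, "IVBW": 14.9}
      }
    },
    {
      "index": 2,
      "label": "infant (0-1 yrs)",
      "specimen_count": 12,
      "levels": {
        "L1": {"AVBH": 8.4, "PVBH": 8.6, "SVBL": 9.4, "IVBL": 9.4, "SVBW": 17.3, "MVBW": 17.6, "IVBW": 17.2},
        "L2": {"AVBH": 8.4, "PVBH": 8.6, "SVBL": 9.5, "IVBL": 9.6, "SVBW": 17.3, "MVBW": 17.8, "IVBW": 17.6},
        "L3": {"AVBH": 8.5, "PVBH": 8.7, "SVBL": 9.5, "IVBL": 9.5, "SVBW": 17.4, "MVBW": 17.8, "IVBW": 17.4},
        "L4": {"AVBH": 8.5, "PVBH": 8.7, "SVBL": 9.6, "IVBL": 9.6, "SVBW": 17.5, "MVBW": 17.9, "IVBW": 17.6},
        "L5": {"AVBH": 8.4, "PVBH": 8.7, "SVBL": 9.6, "IVBL": 9.6, "SVBW": 17.6, "MVBW": 18.0, "IVBW": 17.7}
      }
    },
    {
      "index": 3,
      "label": "toddler (1-3 yrs)",
      "specimen_count": 9,
      "levels": {
        "L1": {"AVBH": 11.7, "PVBH": 11.2, "SVBL": 17.4, "IVBL": 16.3, "SVBW": 28.9, "MVBW": 27.6, "IVBW": 27.2},
        "L2": {"AVBH": 11.7, "PVBH": 11.1, "SVBL": 17.2, "IVBL": 16.3, "SVBW": 28.7, "MVBW": 27.4, "IVBW": 27.2},
        "L3": {"AVBH": 12.1, "PVBH": 11.1, "SVBL": 17.5, "IVBL": 16.2, "SVBW": 29.2, "MVBW": 27.6, "IVBW": 27.0},
        "L4": {"AVBH": 12.5, "PVBH": 11.3, "SVBL": 17.7, "IVBL": 16.2, "SVBW": 29.5, "MVBW": 27.7, "IVBW": 26.9},
        "L5": {"AVBH": 12.5, "PVBH": 10.8, "SVBL": 17.2, "IVBL": 16.3, "SVBW": 28.6, "MVBW": 27.4, "IVBW": 27.1}
      }
    },
    {
      "index": 4,
      "label": "middle childhood (3-7 yrs)",
      "specimen_count": 7,
      "levels": {
        "L1": {"AVBH": 16.1, "PVBH": 16.3, "SVBL": 20.9, "IVBL": 22.6, "SVBW": 31.4, "MVBW": 32.2, "IVBW": 33.9},
        "L2": {"AVBH": 17.6, "PVBH": 15.9, "SVBL": 22.0, "IVBL": 23.2, "SVBW": 33.0, "MVBW": 33.4, "IVBW": 34.9},
        "L3": {"AVBH": 18.5, "PVBH": 16.1, "SVBL": 22.9, "IVBL": 24.5, "SVBW": 34.4, "MVBW": 35.1, "IVBW": 36.8},
        "L4": {"AVBH": 17.0, "PVBH": 14.7, "SVBL": 23.2, "IVBL": 24.7, "SVBW": 34.8, "MVBW": 35.4, "IVBW": 37.1},
        "L5": {"AVBH": 16.7, "PVBH": 13.9, "SVBL": 24.9, "IVBL": 23.1, "SVBW": 36.5, "MVBW": 34.8, "IVBW": 34.0}
      }
    },
    {
      "index": 5,
      "label": "preadolescent (8-12 yrs)",
      "specimen_count": 6,
      "levels": {
        "L1": {"AVBH": 18.9, "PVBH": 18.3, "SVBL": 24.6, "IVBL": 25.6, "SVBW": 32.8, "MVBW": 32.5, "IVBW": 34.1},
        "L2": {"AVBH": 20.3, "PVBH": 19.9, "SVBL": 26.0, "IVBL": 28.5, "SVBW": 34.7, "MVBW": 35.5, "IVBW": 38.0},
        "L3": {"AVBH": 23.0, "PVBH": 18.2, "SVBL": 28.8, "IVBL": 27.4, "SVBW": 38.4, "MVBW": 36.6, "IVBW": 36.5},
        "L4": {"AVBH": 19.8, "PVBH": 16.5, "SVBL": 28.8, "IVBL": 28.0, "SVBW": 38.4, "MVBW": 37.0, "IVBW": 37.3},
        "L5": {"AVBH": 20.3, "PVBH": 16.3, "SVBL": 28.3, "IVBL": 26.5, "SVBW": 37.8, "MVBW": 35.7, "IVBW": 35.3}
      }
    }
  ]
}
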