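{
  "_comment": "Synthetic planted dysregulation regions for the simulation studies. The linear region spans the middle of the 20-gene path; the three ERBB regions are disjoint connected signalling modules (PI3K/AKT-mTOR, RAS/MAPK, NCK/JNK) of the bundled synthetic ERBB-style fixture.",
  "linear_region_1": {"pathway": "linear", "nodes": ["g06", "g07", "g08", "g09", "g10", "g11", "g12"]},
  "erbb_region_1": {"pathway": "erbb", "nodes": ["PIK3CA", "PIK3R1", "AKT1", "MTOR", "RPS6KB1", "EIF4EBP1"]},
  "erbb_region_2": {"pathway": "erbb", "nodes": ["KRAS", "RAF1", "MAP2K1", "MAPK1", "ELK1", "MYC"]},
  "erbb_region_3": {"pathway": "erbb", "nodes": ["NCK1", "PAK1", "MAP2K4", "MAPK8", "JUN"]}
}
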