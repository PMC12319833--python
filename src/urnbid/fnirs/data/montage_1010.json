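{
 "description": "Schematic frontoparietal 10-10 montage: two 8x8 systems, 40 channels, 3 cm separation.",
 "separation_cm": 3.0,
 "sources": {
  "S1": "AF7",
  "S2": "AF3",
  "S3": "AFz",
  "S4": "AF4",
  "S5": "AF8",
  "S6": "F5",
  "S7": "F1",
  "S8": "F2",
  "S9": "C3",
  "S10": "C1",
  "S11": "F3",
  "S12": "F4",
  "S13": "CP2",
  "S14": "P1",
  "S15": "P2",
  "S16": "CP6"
 },
 "detectors": {
  "D1": "Fp1",
  "D2": "Fpz",
  "D3": "Fp2",
  "D4": "F7",
  "D5": "F3",
  "D6": "Fz",
  "D7": "F4",
  "D8": "F8",
  "D9": "C5",
  "D10": "Cz",
  "D11": "C2",
  "D12": "CP1",
  "D13": "F5",
  "D14": "Pz",
  "D15": "P4",
  "D16": "P6"
 },
 "channels": [
  {
   "source": "S1",
   "detector": "D1",
   "region": "l_frontopolar"
  },
  {
   "source": "S1",
   "detector": "D4",
   "region": "l_IFG"
  },
  {
   "source": "S2",
   "detector": "D1",
   "region": "l_frontopolar"
  },
  {
   "source": "S2",
   "detector": "D2",
   "region": "m_frontopolar"
  },
  {
   "source": "S2",
   "detector": "D5",
   "region": "l_DLPFC"
  },
  {
   "source": "S3",
   "detector": "D2",
   "region": "m_frontopolar"
  },
  {
   "source": "S3",
   "detector": "D6",
   "region": "m_SFG"
  },
  {
   "source": "S4",
   "detector": "D2",
   "region": "m_frontopolar"
  },
  {
   "source": "S4",
   "detector": "D3",
   "region": "r_frontopolar"
  },
  {
   "source": "S4",
   "detector": "D7",
   "region": "r_DLPFC"
  },
  {
   "source": "S5",
   "detector": "D3",
   "region": "r_frontopolar"
  },
  {
   "source": "S5",
   "detector": "D8",
   "region": "r_IFG"
  },
  {
   "source": "S6",
   "detector": "D4",
   "region": "l_IFG"
  },
  {
   "source": "S6",
   "detector": "D5",
   "region": "l_DLPFC"
  },
  {
   "source": "S7",
   "detector": "D5",
   "region": "l_DLPFC"
  },
  {
   "source": "S7",
   "detector": "D6",
   "region": "m_SFG"
  },
  {
   "source": "S8",
   "detector": "D6",
   "region": "m_SFG"
  },
  {
   "source": "S8",
   "detector": "D7",
   "region": "r_DLPFC"
  },
  {
   "source": "S6",
   "detector": "D1",
   "region": "l_MFG"
  },
  {
   "source": "S8",
   "detector": "D3",
   "region": "r_MFG"
  },
  {
   "source": "S9",
   "detector": "D9",
   "region": "l_postcentral"
  },
  {
   "source": "S9",
   "detector": "D10",
   "region": "m_central"
  },
  {
   "source": "S10",
   "detector": "D10",
   "region": "m_central"
  },
  {
   "source": "S10",
   "detector": "D11",
   "region": "r_central"
  },
  {
   "source": "S11",
   "detector": "D11",
   "region": "r_central"
  },
  {
   "source": "S11",
   "detector": "D13",
   "region": "l_DLPFC"
  },
  {
   "source": "S12",
   "detector": "D11",
   "region": "r_central"
  },
  {
   "source": "S12",
   "detector": "D13",
   "region": "l_DLPFC"
  },
  {
   "source": "S13",
   "detector": "D12",
   "region": "l_IPL"
  },
  {
   "source": "S13",
   "detector": "D16",
   "region": "r_IPL"
  },
  {
   "source": "S14",
   "detector": "D14",
   "region": "l_SPG"
  },
  {
   "source": "S14",
   "detector": "D12",
   "region": "l_SPG"
  },
  {
   "source": "S15",
   "detector": "D15",
   "region": "r_SPG"
  },
  {
   "source": "S15",
   "detector": "D13",
   "region": "l_MFG"
  },
  {
   "source": "S15",
   "detector": "D16",
   "region": "r_IPL"
  },
  {
   "source": "S16",
   "detector": "D16",
   "region": "r_IPL"
  },
  {
   "source": "S16",
   "detector": "D12",
   "region": "l_IPL"
  },
  {
   "source": "S16",
   "detector": "D15",
   "region": "r_SPG"
  },
  {
   "source": "S9",
   "detector": "D14",
   "region": "l_SPG"
  },
  {
   "source": "S10",
   "detector": "D15",
   "region": "r_SPG"
  }
 ]
}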