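{
 "schema_version": 1,
 "units": "angstrom",
 "frame_tag": "constructed-pocket",
 "anchors": [
  {
   "name": "Asp114:OD",
   "element": "O",
   "role": "acceptor",
   "position": [
    -2.7,
    0.0,
    0.0
   ]
  },
  {
   "name": "Ser193:OG",
   "element": "O",
   "role": "both",
   "position": [
    8.468312223901561,
    0.5544363475983662,
    -0.7444077746549147
   ]
  },
  {
   "name": "Ser193:O",
   "element": "O",
   "role": "acceptor",
   "position": [
    9.268312223901562,
    -0.8455636524016337,
    0.8555922253450854
   ]
  },
  {
   "name": "His393:NE2",
   "element": "N",
   "role": "both",
   "position": [
    5.646758744352693,
    4.4776530440244375,
    -0.3354985977838383
   ]
  },
  {
   "name": "Asn186:OD1",
   "element": "O",
   "role": "acceptor",
   "position": [
    9.66831222390156,
    2.754436347598366,
    1.2555922253450853
   ]
  },
  {
   "name": "Asn186:ND2",
   "element": "N",
   "role": "donor",
   "position": [
    10.468312223901561,
    3.354436347598366,
    0.3555922253450854
   ]
  }
 ],
 "hydrogen_sites": [
  {
   "position": [
    8.259831066495256,
    -2.4984267538487233,
    0.9002640548721245
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    0.5135123631568835,
    -3.781347650769743,
    2.348202863881408
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    3.175985013241758,
    3.526191788918412,
    -2.147835092669822
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    -1.2259424324909598,
    1.873504508372278,
    3.103291404104989
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    -1.180806171997316,
    0.5485272563150576,
    -3.389396211277216
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    -4.246696133706252,
    -1.8370618389591065,
    -1.0241644659869147
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    -2.1749794493090007,
    -3.3273552972928115,
    -1.4209982057584405
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    -5.070567425091755,
    0.635155513188849,
    0.4752999560870783
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    0.6460597981512344,
    6.209590986093652,
    2.809121497506629
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    0.5083408793746024,
    -3.6446021520415885,
    -1.0092318670779519
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    3.4729095472671228,
    1.059457648147279,
    5.15111572089457
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    3.1742588361578092,
    -1.627072183860021,
    4.001989160634399
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    -0.03218931479796838,
    1.640021505540223,
    -3.8558301710172964
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    -2.186724408614344,
    -4.067580282925027,
    1.9985670176758987
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    3.31237121604615,
    6.137179235639289,
    -1.1643650991405083
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    1.859147367001404,
    -0.25554008761249336,
    -3.0825580860145565
   ],
   "tag": "aliphatic_H"
  },
  {
   "position": [
    1.5033352425160642,
    -3.109665701566283,
    -1.3177859498421347
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    1.0156788782572477,
    1.7521736732563575,
    3.5206437142643
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    6.8320162801252895,
    2.203716250578431,
    -2.525769092052794
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    -0.02526385507794772,
    -3.098419368139502,
    0.19699922067127684
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    -4.175791077830763,
    2.7632991785754517,
    0.032628747742707034
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    -3.693411218643906,
    2.4453171742324997,
    2.1372747606883236
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    0.5223806732023789,
    6.179026321256008,
    -2.4879169830246006
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    -4.16783685126303,
    -1.457001958088214,
    2.817682989332918
   ],
   "tag": "aromatic_H"
  },
  {
   "position": [
    1.2886248917990595,
    0.46640511074757135,
    -2.7963169708089284
   ],
   "tag": "aromatic_H"
  }
 ],
 "ring_centroids": [
  [
   5.602782898770694,
   8.259399639163282e-18,
   4.849339769205233
  ],
  [
   4.197217101229307,
   -8.259399639163282e-18,
   -4.849339769205233
  ]
 ]
}
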