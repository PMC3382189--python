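{
 "schema_version": 1,
 "units": "angstrom",
 "frame": "right-handed",
 "frame_tag": "refined-d2-agonist",
 "features": [
  {
   "name": "AspTM3",
   "kind": "cation",
   "center": [
    0.0,
    0.0,
    0.0
   ],
   "radius": 1.2,
   "essential": true,
   "direction": null,
   "direction_tol": 30.0
  },
  {
   "name": "Aro",
   "kind": "aromatic",
   "center": [
    4.9,
    0.0,
    0.0
   ],
   "radius": 0.8040745427831564,
   "essential": true,
   "direction": [
    0.14342508138177412,
    1.6855917630945474e-18,
    0.9896611773888231
   ],
   "direction_tol": 35.0
  },
  {
   "name": "SerTM5",
   "kind": "hbond",
   "center": [
    8.468312223901561,
    0.5544363475983662,
    -0.7444077746549147
   ],
   "radius": 0.6,
   "essential": false,
   "direction": null,
   "direction_tol": 30.0
  }
 ],
 "excluded_volumes": [
  {
   "center": [
    8.259831066495256,
    -2.4984267538487233,
    0.9002640548721245
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    0.5135123631568835,
    -3.781347650769743,
    2.348202863881408
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    3.175985013241758,
    3.526191788918412,
    -2.147835092669822
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    -1.2259424324909598,
    1.873504508372278,
    3.103291404104989
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    -1.180806171997316,
    0.5485272563150576,
    -3.389396211277216
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    -4.246696133706252,
    -1.8370618389591065,
    -1.0241644659869147
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    -2.1749794493090007,
    -3.3273552972928115,
    -1.4209982057584405
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    -5.070567425091755,
    0.635155513188849,
    0.4752999560870783
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    0.6460597981512344,
    6.209590986093652,
    2.809121497506629
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    0.5083408793746024,
    -3.6446021520415885,
    -1.0092318670779519
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    3.4729095472671228,
    1.059457648147279,
    5.15111572089457
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    3.1742588361578092,
    -1.627072183860021,
    4.001989160634399
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    -0.03218931479796838,
    1.640021505540223,
    -3.8558301710172964
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    -2.186724408614344,
    -4.067580282925027,
    1.9985670176758987
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    3.31237121604615,
    6.137179235639289,
    -1.1643650991405083
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    1.859147367001404,
    -0.25554008761249336,
    -3.0825580860145565
   ],
   "radius": 2.0,
   "origin_tag": "aliphatic_H"
  },
  {
   "center": [
    1.5033352425160642,
    -3.109665701566283,
    -1.3177859498421347
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    1.0156788782572477,
    1.7521736732563575,
    3.5206437142643
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    6.8320162801252895,
    2.203716250578431,
    -2.525769092052794
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    -0.02526385507794772,
    -3.098419368139502,
    0.19699922067127684
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    -4.175791077830763,
    2.7632991785754517,
    0.032628747742707034
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    -3.693411218643906,
    2.4453171742324997,
    2.1372747606883236
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    0.5223806732023789,
    6.179026321256008,
    -2.4879169830246006
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    -4.16783685126303,
    -1.457001958088214,
    2.817682989332918
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    1.2886248917990595,
    0.46640511074757135,
    -2.7963169708089284
   ],
   "radius": 1.8,
   "origin_tag": "aromatic_H"
  },
  {
   "center": [
    5.602782898770694,
    8.259399639163282e-18,
    4.849339769205233
   ],
   "radius": 2.5,
   "origin_tag": "ring_centroid"
  },
  {
   "center": [
    4.197217101229307,
    -8.259399639163282e-18,
    -4.849339769205233
   ],
   "radius": 2.5,
   "origin_tag": "ring_centroid"
  }
 ],
 "exclO": {
  "center": [
   3.032659616977254,
   -2.0704982304926567,
   0.3912787606413911
  ],
  "radius": 1.5
 }
}
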