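{
  "type": "FeatureCollection",
  "comment": "Synthetic six-country boundary fixture: crude hand-drawn polygons keyed by real ISO-3 codes, for tests and examples only. Not real borders.",
  "features": [
    {"type": "Feature", "properties": {"iso_a3": "MEX", "name": "Mexico (toy)"},
     "geometry": {"type": "Polygon", "coordinates": [[[-117.0, 32.5], [-97.0, 26.0], [-89.0, 18.0], [-92.0, 14.5], [-105.0, 20.0], [-114.0, 27.0], [-117.0, 32.5]]]}},
    {"type": "Feature", "properties": {"iso_a3": "HND", "name": "Honduras (toy)"},
     "geometry": {"type": "Polygon", "coordinates": [[[-89.3, 16.4], [-83.1, 15.0], [-86.7, 12.9], [-89.3, 14.4], [-89.3, 16.4]]]}},
    {"type": "Feature", "properties": {"iso_a3": "PER", "name": "Peru (toy)"},
     "geometry": {"type": "Polygon", "coordinates": [[[-81.3, -4.5], [-75.0, -0.1], [-70.0, -9.5], [-69.0, -17.5], [-75.5, -15.3], [-81.3, -4.5]]]}},
    {"type": "Feature", "properties": {"iso_a3": "BRA", "name": "Brazil (toy)"},
     "geometry": {"type": "Polygon", "coordinates": [[[-70.0, -4.0], [-50.0, 4.5], [-35.0, -8.0], [-40.0, -22.0], [-53.0, -33.0], [-58.0, -20.0], [-70.0, -10.0], [-70.0, -4.0]]]}},
    {"type": "Feature", "properties": {"iso_a3": "CHL", "name": "Chile (toy)"},
     "geometry": {"type": "Polygon", "coordinates": [[[-70.5, -17.6], [-68.5, -26.0], [-70.0, -45.0], [-74.0, -53.0], [-75.5, -45.0], [-72.0, -26.0], [-70.5, -17.6]]]}},
    {"type": "Feature", "properties": {"iso_a3": "ARG", "name": "Argentina (toy)"},
     "geometry": {"type": "MultiPolygon", "coordinates": [[[[-68.0, -22.0], [-58.0, -24.0], [-57.0, -38.0], [-65.0, -55.0], [-70.5, -50.0], [-70.0, -30.0], [-68.0, -22.0]]], [[[-68.5, -54.8], [-65.2, -54.9], [-66.5, -55.3], [-68.5, -54.8]]]]}}
  ]
}
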