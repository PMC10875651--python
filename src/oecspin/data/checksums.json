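{
 "hfc_mn55.csv": "73ab81754d393e150737e8057c3b91f8909f4e39354d7c753a84509617c84e29",
 "hfc_n14.csv": "f7b9f02409ce5ec6a87e44eb734a4243d823dd5c1231f3d0bfcd661a74a12b3c",
 "hfc_o17.csv": "ba8ad7ab0124f9555990b3cc0832943dc82ebc3563ca4bbbcccedc31ef1c322e",
 "models/A1.json": "f3a5d6445910fc7552186aeb761f18f2fa7c389e3cac7260876685ef129cba9d",
 "models/A10.json": "22ba97d8b7a8eb843eeb5c4887160c4cae47e724d612c1db140282586eab9be3",
 "models/A2.json": "2f4cab688286fb47c97c36aa37dadd135f7ff235f380ac2961641c0b060f30fb",
 "models/A3.json": "2fc034fa50861ac2aba766693c8ee26dc2ce328bb4194313c1d6c60cabd047a3",
 "models/A4.json": "f328911cdf6a5bbccf53213bc41a3fdeb6e81b9d7b0676db60a9a453c866c1d5",
 "models/A5.json": "949aa470c3ccdca1941ba5e36b7fdbef04549cd36ed164bc044a511746eff7c9",
 "models/A6.json": "2c7d5805a933ef22ab2975946f3f0b50c9e161fbd171011ffc72f298e430180f",
 "models/A7.json": "f8348806b26298bbde06f1f6efb8ff8c1bca8655cf02b0a417397e92f21eb225",
 "models/A8.json": "5e0071daa78f2f8f1971cbdd21d4457b3b768ba9e81ba62e71a2664fb2549b87",
 "models/A9.json": "cb299fe75e0fde36c2f2137fb064a4d7e4e904e6c4e767ac05c02bfbc10ea076",
 "models/B1.json": "09ea8ce0d22fbdc5778a932501879c7cf7cbd69d0c2a54826211e8f32b337445",
 "models/B2.json": "06a38b2c2e110826fb0e66c66fec09d67be571e99b7ba18900716388c8f081c5",
 "models/B3.json": "2acf991ee129323726e52babfbfb07556c2be1131699af8c800df36d63c6599c",
 "models/B4.json": "3f326f05df353049cacbf799ba52e23699c38b6c8b34dd8adb43eced49b9ea17",
 "models/C1.json": "75201c20b6cd726b83bd8a8073d357c2c3a303905a4fbff259283a80e9d4ff76",
 "models/C2.json": "32ed904497b7bdbd42d7866509fa46b9066841fa4a529a03516ba3a7cf17d55d",
 "models/C3.json": "9c8f5616161437bb60c570e041c6e56753613780631c58d360208b935cc63645",
 "models/D1.json": "4f808bf41b26f3b61be0bd5167331251a690d7da6a4486883d61cf5623083724",
 "models/D2.json": "12159cb3ba3696a356b7bf8db7e0488c9af3c0532685e7f31dc710686ec8cb9d",
 "models/D3.json": "6a553e6c60eba6e318d656461c8c67f35c2440f411c7edc9200d6d4a5e006a3c",
 "models/D4.json": "e3d5c64eb87151aa3eeece5cd6b0ce468c131c0c95d9186861e768d6dca76134",
 "models/D5.json": "10fa5645b6f1bae0c4fd2f2f11e06f81c1a21bd8d89132d19b8467cd48f0ce02",
 "models/D6.json": "2c0558aa49b1b7a3264eb12399d5950863908df6f2f4967c03e0713c2aa63486",
 "models/D7.json": "7dc997b095e95aaec37c6f798b3b75d4847e1a61c89618db2347b70ede8c4a31",
 "models/D8.json": "3715e6f9fd5b95f98e259e13a3616509e0dbf5585bab932a67b11f3ced9b1a4c",
 "models/E1.json": "8fdff79eda4e3516ec4a7afac3985123fb00cf8c7e5486ce98109f9de0e56e7c",
 "models/E2.json": "44986a32a2505389dcfa39dfda6657f3ed68662cee7dc1194e51de1c7c4d4718",
 "models/E3.json": "96453cc35d9a2bf79d25e8988c0ecd4c388717f402eabb9b05feccab48db5a51",
 "models/E4.json": "2d49c8fb981d8e7cbefab732233d1a17d0f3f961010496d4ac80bca819093e7c",
 "models/S2.json": "bb06ac53aa76b4ffd1ebb5b44eee6cb5384bc5b8fc5e32b45206e5f2d5156ab3",
 "models/S2H.json": "3e58b4dcf4fb2371ac813a6498b6d023004ebad4830a18ed965d68fb02f282c7",
 "references.json": "039197d3c762755ea1484cb00cc228172b53e944a28b5119e5e0e8dc08e64424"
}
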