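Smith
Jones
Williams
Brown
Taylor
Davies
Wilson
Evans
Thomas
Johnson
Roberts
Walker
Wright
Robinson
Thompson
White
Hughes
Edwards
Green
Hall
Lewis
Harris
Clarke
Patel
Jackson
Wood
Turner
Martin
Cooper
Hill
Ward
Morris
Moore
Clark
Lee
King
Baker
Khan
Singh
Ahmed
Okafor
Mensah
Nowak
Kowalski
O'Brien
Murphy
Kelly
Begum
Ali
Hussain
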