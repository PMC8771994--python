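import itertools

import pytest

from coldroute import (
    Facility,
    Instance,
    Parameters,
    Product,
    RoadNetwork,
    Vehicle,
    example_instance,
)


def make_instance(
    facility_names=("Depot", "A", "B"),
    depot="Depot",
    distances=None,
    road_classes=None,
    default_distance=40.0,
    default_class="Partially paved",
    demand=None,
    cold_demand=None,
    vehicles=None,
    start="08:00",
    ret="18:00",
    weight_time=5,
    service=0.0,
    fuel_price=1.5,
    per_diem=15.0,
):
    """Small hand-built instance: one cold and one ambient product.

    ``cold_demand``/``demand`` map facility -> units of the 2 L cold
    product / 1 L ambient product (default 10/10 per non-depot facility).
    """
    products = [
        Product("Cold vials", requires_cold=True, unit_volume=2.0),
        Product("Dry kits", requires_cold=False, unit_volume=1.0),
    ]
    facilities = [Facility(n, 1000.0, 1000.0) for n in facility_names]
    dem = {}
    for n in facility_names:
        base = 0 if n == depot else 10
        dem[(n, "Cold vials")] = (cold_demand or {}).get(n, base)
        dem[(n, "Dry kits")] = (demand or {}).get(n, base)
    dist, road = {}, {}
    for a, b in itertools.combinations(facility_names, 2):
        dist[(a, b)] = (distances or {}).get((a, b), (distances or {}).get((b, a), default_distance))
        road[(a, b)] = (road_classes or {}).get((a, b), (road_classes or {}).get((b, a), default_class))
    if vehicles is None:
        vehicles = [Vehicle("Truck", True, "Good", 500.0, 500.0, 0.2, 2)]
    params = Parameters(depot_name=depot, start_time=start, return_time=ret,
                        weight_time=weight_time, service_hours_per_stop=service,
                        fuel_price=fuel_price, per_diem_rate=per_diem)
    return Instance(parameters=params, products=products, facilities=facilities,
                    demand=dem, vehicles=vehicles,
                    network=RoadNetwork(distance=dist, road_class=road))


@pytest.fixture
def province():
    return example_instance()


@pytest.fixture
def tiny():
    return make_instance()
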